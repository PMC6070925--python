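"""Synthetic reference proteins used as alignment anchors and mining baits.

The real reference proteins (S. cerevisiae isomaltase IMA1, the O. polymorpha
MAL1/MAL2 proteins, a MAL-activator) are not bundled; instead this module
builds deterministic **synthetic stand-ins**: random amino-acid sequences of
realistic length, with the nine substrate-binding-pocket residues of the
isomaltase signature (YVGSLMQDE) written into the IMA1-equivalent anchor
positions 158/216/217/218/219/278/279/307/411 of the glucosidase scaffold.
Every position-mapping, signature-extraction and homology-mining operation in
the package is anchored to these scaffolds, so results are internally
consistent; residue numbering follows the IMA1 convention used throughout the
α-glucosidase literature.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: 1-based IMA1-style anchor positions of the nine signature residues.
ANCHOR_POSITIONS = (158, 216, 217, 218, 219, 278, 279, 307, 411)

#: Signature of the scaffold itself (isomaltase-type, as in Sc IMA1/IMA2).
SCAFFOLD_SIGNATURE = "YVGSLMQDE"

_SCAFFOLD_LENGTH = 589  # length of Sc IMA1
_AGT_LENGTH = 550  # typical alpha-glucoside permease length
_ACT_LENGTH = 480  # typical Zn(2)-Cys(6) MAL-activator length


def _random_protein(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@lru_cache(maxsize=None)
def glucosidase_scaffold() -> str:
    """Synthetic 589-aa α-glucosidase scaffold (IMA1 stand-in).

    Carries Y158, V216, G217, S218, L219, M278, Q279, D307 and E411 so that
    signature extraction against it returns ``YVGSLMQDE`` exactly.
    """
    seq = list(_random_protein(_SCAFFOLD_LENGTH, seed=715101))
    for pos, aa in zip(ANCHOR_POSITIONS, SCAFFOLD_SIGNATURE):
        seq[pos - 1] = aa
    return "".join(seq)


@lru_cache(maxsize=None)
def transporter_scaffold() -> str:
    """Synthetic 550-aa α-glucoside transporter (MAL2-type permease stand-in)."""
    return _random_protein(_AGT_LENGTH, seed=715102)


@lru_cache(maxsize=None)
def activator_scaffold() -> str:
    """Synthetic 480-aa MAL-activator (Zn(2)-Cys(6) regulator stand-in)."""
    return _random_protein(_ACT_LENGTH, seed=715103)
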