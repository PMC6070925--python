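"""Dayhoff (1978) empirical amino-acid substitution model constants.

Exchangeabilities and equilibrium frequencies of the classic Dayhoff PAM
model, as distributed in PAML's ``dayhoff.dat`` (lower triangle of the
symmetric exchangeability matrix, column-major, amino acids in the order
``ARNDCQEGHILKMFPSTWYV``).
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# 190 below-diagonal exchangeabilities s[i][j], column-major (j < i).
EXCHANGEABILITIES = (
    27.0, 98.0, 120.0, 36.0, 89.0, 198.0, 240.0, 23.0, 65.0, 41.0,
    26.0, 72.0, 18.0, 250.0, 409.0, 371.0, 0.0, 24.0, 208.0, 32.0,
    0.0, 23.0, 246.0, 1.0, 9.0, 240.0, 64.0, 15.0, 464.0, 90.0,
    14.0, 103.0, 154.0, 26.0, 201.0, 8.0, 24.0, 905.0, 0.0, 103.0,
    148.0, 139.0, 535.0, 77.0, 34.0, 318.0, 1.0, 14.0, 42.0, 495.0,
    229.0, 23.0, 95.0, 15.0, 0.0, 134.0, 1153.0, 125.0, 86.0, 24.0,
    0.0, 71.0, 0.0, 0.0, 13.0, 95.0, 66.0, 0.0, 0.0, 18.0,
    0.0, 0.0, 11.0, 28.0, 44.0, 0.0, 0.0, 0.0, 0.0, 19.0,
    161.0, 16.0, 0.0, 96.0, 49.0, 716.0, 28.0, 606.0, 18.0, 73.0,
    153.0, 114.0, 0.0, 153.0, 56.0, 53.0, 0.0, 0.0, 35.0, 81.0,
    43.0, 61.0, 11.0, 83.0, 30.0, 0.0, 51.0, 79.0, 34.0, 0.0,
    22.0, 37.0, 10.0, 0.0, 7.0, 27.0, 17.0, 15.0, 34.0, 234.0,
    30.0, 0.0, 0.0, 54.0, 7.0, 44.0, 26.0, 0.0, 48.0, 94.0,
    35.0, 22.0, 27.0, 127.0, 44.0, 257.0, 46.0, 336.0, 196.0, 12.0,
    24.0, 192.0, 0.0, 37.0, 889.0, 18.0, 527.0, 157.0, 32.0, 17.0,
    33.0, 46.0, 28.0, 175.0, 243.0, 0.0, 33.0, 96.0, 136.0, 0.0,
    13.0, 10.0, 92.0, 17.0, 62.0, 104.0, 0.0, 0.0, 258.0, 11.0,
    46.0, 13.0, 76.0, 698.0, 12.0, 245.0, 78.0, 0.0, 0.0, 48.0,
    550.0, 75.0, 34.0, 30.0, 0.0, 42.0, 157.0, 61.0, 0.0, 28.0,
)

# Equilibrium amino-acid frequencies (same order), summing to 1.
FREQUENCIES = (
    0.08712691287308713, 0.04090395909604091, 0.04043195956804044, 0.04687195312804687,
    0.033473966526033475, 0.03825496174503826, 0.04952995047004953, 0.08861191138808862,
    0.033617966382033626, 0.03688596311403689, 0.08535691464308537, 0.08048191951808048,
    0.014752985247014754, 0.03977196022803978, 0.05067994932005069, 0.06957693042306959,
    0.05854194145805854, 0.010493989506010494, 0.02991597008402992, 0.06471793528206472,
)
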