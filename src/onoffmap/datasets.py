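"""Bundled per-volume cell-class counts from thirteen imaged volumes of mouse
primary visual cortex.

Each row summarises one two-photon imaging volume: the number of
mono-contrast ON and OFF cells, the number of dual-polarity cells (with the
simple/complex split within that group), and the correlation between
fluctuation maps computed from the top and bottom halves of the optical
sections (the columnarity check; ``layers_sig`` marks significance at 0.01).
These counts serve as reference input for pooled population-composition
summaries.
"""

from io import StringIO

import pandas as pd

_TABLE = """\
dataset,n_planes,n_on,n_off,n_dual,n_simple,n_complex,layers_r,layers_sig
1,4,479,346,144,82,62,0.12,True
2,7,821,936,415,248,167,-0.01,False
3,6,274,294,47,33,14,0.29,True
4,5,483,706,350,159,191,0.27,True
5,8,319,549,95,64,31,0.15,True
6,8,447,600,232,136,96,0.03,True
7,6,379,895,307,131,176,0.31,True
8,7,692,3037,1071,376,695,0.43,True
9,8,383,1992,293,146,147,0.28,True
10,7,317,1178,272,124,148,0.63,True
11,8,310,524,62,27,35,0.55,True
12,6,974,1263,419,163,256,0.41,True
13,6,662,1052,723,316,407,0.17,True
"""


def study_datasets() -> pd.DataFrame:
    """Return the thirteen-volume summary table, one row per volume."""
    return pd.read_csv(StringIO(_TABLE))
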