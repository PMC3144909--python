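"""Reference panda–human benchmark values shipped as package data.

Two small tables from the published nine-mammal appetite-reward gene screen
anchor the validation suite and the reproduction script:

* ``coding_screen_panda_human.tsv`` — the six proteins that passed the dual
  >75% coverage/consensus filter, with their structure-coverage and
  panda-vs-human consensus fractions and printed percentages.
* ``kozak_flags_panda_human.tsv`` — the seven genes whose initiation-context
  flag pattern (-3 purine, +4 G) differs between panda and human, with the
  published per-species flags and strength letters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .kozak import IDX_MINUS3, IDX_PLUS1, IDX_PLUS4, WINDOW_LEN


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("orthoscreen.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_coding_benchmark() -> pd.DataFrame:
    """Coverage/consensus fractions and printed percentages, one row per
    screened gene."""
    return _load("coding_screen_panda_human.tsv")


def load_kozak_benchmark() -> pd.DataFrame:
    """Published initiation-context flags and strengths, one row per
    (gene, species)."""
    return _load("kozak_flags_panda_human.tsv")


def window_from_flags(atg: bool, g_plus4: bool, r_minus3: bool) -> str:
    """A 30-nt initiation context realizing a given flag pattern, used to
    replay published flag rows through the classifier."""
    w = ["C"] * WINDOW_LEN
    w[IDX_PLUS1:IDX_PLUS1 + 3] = list("ATG" if atg else "CTG")
    w[IDX_PLUS4] = "G" if g_plus4 else "C"
    w[IDX_MINUS3] = "A" if r_minus3 else "C"
    return "".join(w)
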