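"""Bundled reference data: the published miR-378a-3p differential targetome.

Two Ago2-RIP-Chip screens in the ST486 Burkitt-lymphoma line are shipped as
plain TSV tables of replicate-averaged IP/T enrichment ratios:

* ``overexpression`` — miR-378a overexpression (pCDH-378a) versus empty
  vector (pCDH-EV); the empty-vector ratio is the comparison's denominator
  and was floored at 1.0.
* ``inhibition`` — scrambled control (mZip-SCR) versus miR-378a-3p
  inhibition (mZip-378a-3p); the inhibition ratio is the denominator and was
  floored at 1.0.

Each row carries the gene symbol, the transcript id, both ratios, the fold
change as originally printed (``fc_printed``, for cross-checking — the
pipeline recomputes FC from the ratio columns), per-region seed-site
annotations in short notation (7mA1/7m8/8m), and a growth-related GO flag.
The mature miR-378a-3p sequence (miRBase v21) is provided for seed-pattern
construction.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ripchip import EnrichmentTable
from .seedscan import MatureMiRNA

#: mature miR-378a-3p, miRBase v21, 5'->3'
MIR_378A_3P = "ACUGGACUUGGAGUCAGAAGGC"

#: condition labels per screen: (numerator, denominator) of the comparison
SCREEN_CONDITIONS = {
    "overexpression": ("pCDH-378a", "pCDH-EV"),
    "inhibition": ("mZip-SCR", "mZip-378a-3p"),
}

_FILES = {
    "overexpression": "targetome_overexpression.tsv",
    "inhibition": "targetome_inhibition.tsv",
}


def mir378a_3p() -> MatureMiRNA:
    """The mature miR-378a-3p sequence as a :class:`MatureMiRNA`."""
    return MatureMiRNA("hsa-miR-378a-3p", MIR_378A_3P)


def load_targetome_screen(screen: str) -> pd.DataFrame:
    """Load one of the bundled differential-targetome ratio tables.

    ``screen`` is ``"overexpression"`` or ``"inhibition"``.  The returned
    frame's ``attrs`` carry the comparison's numerator/denominator condition
    labels.
    """
    if screen not in _FILES:
        raise ValueError(f"unknown screen {screen!r}; choose from {sorted(_FILES)}")
    path = resources.files("mirtargetome").joinpath("data", _FILES[screen])
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    num, den = SCREEN_CONDITIONS[screen]
    df.attrs["numerator"] = num
    df.attrs["denominator"] = den
    df.attrs["screen"] = screen
    return df


def screen_enrichment(screen: str) -> EnrichmentTable:
    """The ratio table of a screen as an :class:`EnrichmentTable`.

    Transcript ids serve as probe ids; the denominator condition is floored
    at 1.0 (a no-op on the printed values, which are already floored).
    """
    df = load_targetome_screen(screen)
    num, den = SCREEN_CONDITIONS[screen]
    return EnrichmentTable.from_ratios(
        df,
        condition_columns={num: "ratio_numerator", den: "ratio_denominator"},
        floor_condition=den,
    )
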