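"""Ago2-RIP-Chip differential targetome analysis.

An Ago2 RNA immunoprecipitation followed by expression microarray profiling
("RIP-Chip") measures, per probe, a total-RNA (T) and an IP-fraction signal
in each condition.  Transcripts loaded into the RNA-induced silencing
complex are enriched in the IP fraction, and transcripts whose IP/T
enrichment rises (on miRNA overexpression) or falls (on miRNA inhibition)
by at least two-fold are called members of that miRNA's differential
targetome.

Pipeline: quantile normalization -> three-rule probe filtering (present
flags, expression percentile in the T fractions, duplicate consistency) ->
replicate-averaged IP/T ratios with a 1.0 floor on the comparison's
denominator condition -> cross-condition fold-change calling collapsed to
genes -> optional seed-site and growth-GO annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seedscan import (
    REGIONS,
    MatureMiRNA,
    TranscriptModel,
    scan_transcript,
    seed_patterns,
)

logger = logging.getLogger(__name__)

FRACTION_TOTAL = "T"
FRACTION_IP = "IP"

# short labels used in human-readable site-annotation columns
SITE_SHORT = {"7mer-A1": "7mA1", "7mer-m8": "7m8", "8mer": "8m"}
_SITE_ORDER = ("7mer-A1", "7mer-m8", "8mer")


@dataclass
class ArrayDataset:
    """Two-fraction microarray signals with per-sample metadata.

    ``signal``: probes x samples, strictly positive.
    ``present``: boolean detection flags, same shape as ``signal``.
    ``samples``: one row per sample with columns condition / fraction /
    replicate; fraction is ``"T"`` or ``"IP"``.
    ``probe_info``: optional probe -> (gene, transcript) map.
    """

    signal: pd.DataFrame
    present: pd.DataFrame
    samples: pd.DataFrame
    probe_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.signal.columns) != list(self.samples.index):
            raise ValueError("signal columns must match the sample table index")
        if self.present.shape != self.signal.shape:
            raise ValueError("present flags must have the signal's shape")
        bad = set(self.samples["fraction"]) - {FRACTION_TOTAL, FRACTION_IP}
        if bad:
            raise ValueError(f"unknown fraction label(s): {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.signal.index)

    def sample_names(self, condition: str | None = None, fraction: str | None = None):
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if fraction is not None:
            mask &= self.samples["fraction"] == fraction
        return list(self.samples.index[mask])

    def gene_of(self, probe: str) -> str:
        if self.probe_info is not None and probe in self.probe_info.index:
            g = self.probe_info.loc[probe, "gene"]
            if isinstance(g, str) and g:
                return g
        return probe

    def transcript_of(self, probe: str) -> str:
        if self.probe_info is not None and probe in self.probe_info.index:
            t = self.probe_info.loc[probe, "transcript"]
            if isinstance(t, str) and t:
                return t
        return probe


def quantile_normalize(ds: ArrayDataset) -> ArrayDataset:
    """Replace each sample's values by the cross-sample mean of its rank.

    After the transform, the sorted value vector is identical in every
    sample; within-sample rank order is preserved, and ties receive the mean
    of the reference values over the tied span.
    """
    x = ds.signal.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    if (x <= 0).any():
        raise ValueError("signals must be positive")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col = np.empty(x.shape[0])
        col[order] = reference
        # ties: average the reference values across each tied span
        vals, inverse = np.unique(x[:, j], return_inverse=True)
        if len(vals) < x.shape[0]:
            sums = np.bincount(inverse, weights=col)
            counts = np.bincount(inverse)
            col = (sums / counts)[inverse]
        out[:, j] = col
    return ArrayDataset(
        signal=pd.DataFrame(out, index=ds.signal.index, columns=ds.signal.columns),
        present=ds.present.copy(),
        samples=ds.samples.copy(),
        probe_info=None if ds.probe_info is None else ds.probe_info.copy(),
    )


@dataclass
class FilteredProbeSet:
    """Probes surviving the three filters, with a per-probe rule audit."""

    retained: list[str]
    audit: pd.DataFrame  # boolean columns: present_all, percentile_ok, duplicates_ok


def filter_probes(
    ds: ArrayDataset,
    percentile_floor: float = 25.0,
    duplicate_fc_max: float = 2.0,
) -> FilteredProbeSet:
    """Apply the three probe-selection rules of the RIP-Chip workflow.

    A probe is retained iff (1) it is flagged present in all samples; (2) its
    signal is at or above the ``percentile_floor``-th percentile of all probe
    signals within that sample in at least half of the total (T) fraction
    samples; and (3) every replicate pair within the same (condition,
    fraction) differs by strictly less than ``duplicate_fc_max``-fold.
    """
    t_samples = ds.sample_names(fraction=FRACTION_TOTAL)
    if not t_samples:
        raise ValueError("dataset has no total (T) fraction samples")

    present_all = ds.present.all(axis=1)

    t_sig = ds.signal[t_samples]
    floors = t_sig.quantile(percentile_floor / 100.0, axis=0)
    n_pass = (t_sig >= floors).sum(axis=1)
    percentile_ok = 2 * n_pass >= len(t_samples)  # ties (exactly half) pass

    duplicates_ok = pd.Series(True, index=ds.signal.index)
    for (_cond, _frac), grp in ds.samples.groupby(["condition", "fraction"]):
        cols = list(grp.index)
        if len(cols) < 2:
            continue
        sub = ds.signal[cols]
        ratio = sub.max(axis=1) / sub.min(axis=1)
        duplicates_ok &= ratio < duplicate_fc_max  # strict: a 2.0-fold pair fails

    audit = pd.DataFrame(
        {
            "present_all": present_all,
            "percentile_ok": percentile_ok,
            "duplicates_ok": duplicates_ok,
        }
    )
    retained = list(audit.index[audit.all(axis=1)])
    return FilteredProbeSet(retained=retained, audit=audit)


@dataclass
class EnrichmentTable:
    """Replicate-averaged IP/T enrichment per (probe, condition).

    ``table`` columns: probe, gene, transcript, condition, mean_T, mean_IP,
    ratio, floored_ratio.  ``floored_ratio`` is max(ratio, 1.0) for the
    designated floor condition (a comparison's denominator) and equals
    ``ratio`` elsewhere.
    """

    table: pd.DataFrame
    floor_condition: str | None = None

    def conditions(self) -> list[str]:
        return list(pd.unique(self.table["condition"]))

    @classmethod
    def from_ratios(
        cls,
        ratios: pd.DataFrame,
        condition_columns: dict[str, str],
        floor_condition: str | None = None,
        probe_column: str | None = None,
        gene_column: str = "gene",
        transcript_column: str = "transcript",
    ) -> "EnrichmentTable":
        """Build an enrichment table from already-computed IP/T ratio columns.

        ``condition_columns`` maps condition label -> ratio column name.
        Useful for re-analysing published ratio tables where only the ratios
        (not the underlying fraction signals) are available; mean_IP is set to
        the ratio and mean_T to 1.
        """
        rows = []
        for _, r in ratios.iterrows():
            probe = r[probe_column] if probe_column else r[transcript_column]
            for cond, col in condition_columns.items():
                ratio = float(r[col])
                floored = max(ratio, 1.0) if cond == floor_condition else ratio
                rows.append(
                    {
                        "probe": probe,
                        "gene": r[gene_column],
                        "transcript": r[transcript_column],
                        "condition": cond,
                        "mean_T": 1.0,
                        "mean_IP": ratio,
                        "ratio": ratio,
                        "floored_ratio": floored,
                    }
                )
        return cls(table=pd.DataFrame(rows), floor_condition=floor_condition)


def compute_enrichment(
    ds: ArrayDataset,
    filtered: FilteredProbeSet | None = None,
    floor_condition: str | None = None,
    symmetric_floor: bool = False,
) -> EnrichmentTable:
    """Replicate-averaged IP/T ratio per (probe, condition), with flooring.

    Ratios below 1.0 are raised to 1.0 in the ``floor_condition`` (the
    comparison's denominator), so that depletion from RISC can only shrink,
    never inflate, a cross-condition fold change.  ``symmetric_floor`` floors
    every condition instead (sensitivity analysis).
    """
    probes = ds.probe_ids if filtered is None else filtered.retained
    conditions = list(pd.unique(ds.samples["condition"]))
    if floor_condition is not None and floor_condition not in conditions:
        raise ValueError(f"unknown floor condition {floor_condition!r}")
    rows = []
    for cond in conditions:
        t_cols = ds.sample_names(condition=cond, fraction=FRACTION_TOTAL)
        ip_cols = ds.sample_names(condition=cond, fraction=FRACTION_IP)
        if not t_cols or not ip_cols:
            raise ValueError(f"condition {cond!r} is missing a T or IP fraction")
        mean_t = ds.signal.loc[probes, t_cols].mean(axis=1)
        mean_ip = ds.signal.loc[probes, ip_cols].mean(axis=1)
        ratio = mean_ip / mean_t
        floor_here = symmetric_floor or cond == floor_condition
        floored = np.maximum(ratio, 1.0) if floor_here else ratio
        for probe in probes:
            rows.append(
                {
                    "probe": probe,
                    "gene": ds.gene_of(probe),
                    "transcript": ds.transcript_of(probe),
                    "condition": cond,
                    "mean_T": float(mean_t[probe]),
                    "mean_IP": float(mean_ip[probe]),
                    "ratio": float(ratio[probe]),
                    "floored_ratio": float(floored[probe]),
                }
            )
    return EnrichmentTable(table=pd.DataFrame(rows), floor_condition=floor_condition)


def differential_targetome(
    et: EnrichmentTable,
    numerator: str,
    denominator: str,
    fc_threshold: float = 2.0,
    direction: str | None = None,
) -> pd.DataFrame:
    """Call the differential targetome between two conditions.

    Per probe, FC = IP/T ratio in the numerator condition divided by the
    *floored* ratio in the denominator condition.  Probes with FC >=
    ``fc_threshold`` (on unrounded values) are collapsed to genes: each gene
    reports its maximum-FC probe and the number of passing probes.  Records
    are sorted by FC descending, ties by gene label.
    """
    tab = et.table
    conds = set(tab["condition"])
    for c in (numerator, denominator):
        if c not in conds:
            raise ValueError(f"condition {c!r} not present in the enrichment table")
    num = tab[tab["condition"] == numerator].set_index("probe")
    den = tab[tab["condition"] == denominator].set_index("probe")
    common = num.index.intersection(den.index)
    num, den = num.loc[common], den.loc[common]
    fc = num["ratio"] / den["floored_ratio"]
    passing = fc[fc >= fc_threshold]
    records = pd.DataFrame(
        {
            "gene": num.loc[passing.index, "gene"],
            "transcript": num.loc[passing.index, "transcript"],
            "ratio_denominator": den.loc[passing.index, "floored_ratio"],
            "ratio_numerator": num.loc[passing.index, "ratio"],
            "fc": passing,
        }
    )
    if records.empty:
        out = records.assign(n_probes=pd.Series(dtype=int))
    else:
        # collapse to genes: keep the max-FC probe, count passing probes
        records = records.sort_values(["fc", "transcript"], ascending=[False, True])
        n_probes = records.groupby("gene").size()
        out = records.groupby("gene", sort=False).head(1).copy()
        out["n_probes"] = out["gene"].map(n_probes)
    out["direction"] = direction
    out = out.sort_values(["fc", "gene"], ascending=[False, True]).reset_index(drop=True)
    out.attrs["numerator"] = numerator
    out.attrs["denominator"] = denominator
    out.attrs["fc_threshold"] = fc_threshold
    return out


def threshold_count_table(
    et: EnrichmentTable,
    comparisons: list[tuple[str, str]],
    thresholds: tuple[float, ...] = (2.0, 4.0, 8.0),
) -> pd.DataFrame:
    """Probe counts per condition and gene counts per comparison at FC cutoffs.

    Rows are indexed by threshold; per-condition columns count probes with
    IP/T ratio >= threshold, and per-comparison columns (labelled
    "num/den") count genes called by ``differential_targetome`` at that
    threshold.
    """
    cols: dict[str, list[int]] = {}
    for cond in et.conditions():
        ratios = et.table.loc[et.table["condition"] == cond, "ratio"]
        cols[cond] = [int((ratios >= t).sum()) for t in thresholds]
    for num, den in comparisons:
        label = f"{num}/{den}"
        cols[label] = [
            len(differential_targetome(et, num, den, fc_threshold=t))
            for t in thresholds
        ]
    return pd.DataFrame(cols, index=pd.Index(thresholds, name="threshold"))


def annotate_targetome(
    records: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
    mirna: MatureMiRNA,
    growth_go: dict[str, bool] | set[str] | None = None,
) -> pd.DataFrame:
    """Add per-region seed-site columns and a growth-GO flag to targetome records.

    Site types found by the seed scanner are listed per region using the
    conventional short labels (7mA1 / 7m8 / 8m), joined by "/".  Records
    whose transcript is unavailable get empty annotations (logged).
    """
    patterns = seed_patterns(mirna)
    out = records.copy()
    site_cols = {r: [] for r in REGIONS}
    growth = []
    for _, rec in out.iterrows():
        tx_id = rec["transcript"]
        found: dict[str, list[str]] = {r: [] for r in REGIONS}
        if tx_id in transcripts:
            for m in scan_transcript(transcripts[tx_id], patterns):
                if m.site_type not in found[m.region]:
                    found[m.region].append(m.site_type)
        else:
            logger.info("no transcript sequence for %s (%s); left unannotated",
                        rec["gene"], tx_id)
        for r in REGIONS:
            types = sorted(found[r], key=_SITE_ORDER.index)
            site_cols[r].append("/".join(SITE_SHORT[t] for t in types))
        if growth_go is None:
            growth.append(False)
        elif isinstance(growth_go, set):
            growth.append(rec["gene"] in growth_go)
        else:
            growth.append(bool(growth_go.get(rec["gene"], False)))
    for r in REGIONS:
        out[f"sites_{r.lower()}"] = site_cols[r]
    out["growth_go"] = growth
    return out
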