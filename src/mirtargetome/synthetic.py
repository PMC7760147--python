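"""Synthetic data generators with planted ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — negative-binomial miRNA counts with planted log2 fold changes,
log-normal two-fraction array signals with planted IP enrichment, random
transcripts with seed sites written at known coordinates, exponential GFP
competition trajectories with replicate random effects, and duplicate-well
luciferase readings — so every downstream caller can be verified at desk
scale against known truth.  All randomness flows from the single integer
seed in each config through one numpy Generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ripchip import ArrayDataset
from .seedscan import (
    REGION_3UTR,
    SITE_TYPES,
    MatureMiRNA,
    TranscriptModel,
    seed_patterns,
)
from .smallrna import CountMatrix


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator; only the relevant field is filled."""

    de_mirnas: dict[str, float] | None = None  # id -> true log2 fold change
    target_probes: dict[str, float] | None = None  # id -> true IP log2 effect
    absent_probes: set[str] | None = None
    inconsistent_probes: set[str] | None = None
    site_positions: list[tuple[str, int, str, str]] | None = None
    gfp_slope_diff: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# small RNA counts


@dataclass
class SmallRnaSimConfig:
    """Negative-binomial miRNA count simulator settings.

    Defaults emulate a small comparison of four tumour cell lines against
    three sorted normal B-cell samples at a few million reads per library,
    with 10% of miRNAs carrying a 4-fold planted change.
    """

    n_mirnas: int = 500
    n_per_group: tuple[int, int] = (4, 3)
    library_size_mean: float = 2e6
    dispersion: float = 0.2
    n_de: int = 50
    de_log2fc: float = 2.0
    seed: int = 0
    abundance_sigma: float = 1.8  # log-sd of baseline abundances across miRNAs
    library_size_cv: float = 0.3
    group_labels: tuple[str, str] = ("BL", "GCB")

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0 or min(self.n_per_group) <= 0:
            raise ValueError("n_mirnas and group sizes must be positive")
        if self.n_de < 0 or self.n_de > self.n_mirnas:
            raise ValueError("need 0 <= n_de <= n_mirnas")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")


def simulate_smallrna_counts(cfg: SmallRnaSimConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Simulate a two-group miRNA count matrix with planted fold changes.

    Baseline abundances are log-normal across miRNAs; planted miRNAs have the
    effect split symmetrically between the groups (x 2^(fc/2) in group one,
    x 2^(-fc/2) in group two) so their expected group-mean ratio is exactly
    2^de_log2fc.  The unplanted complement is rescaled so each group's
    expected proportions still sum to one: sequencing reads are compositional
    and a per-million normalization forces exactly this compensation, so the
    planted ratio also holds in expectation on the RPM scale.  Effects are
    planted on miRNAs abundant enough to survive a raw-count floor in the
    depleted group (real differential calls are only made on quantifiable
    miRNAs) but not so dominant that a single species would absorb the
    library.  Counts are gamma-Poisson (negative binomial) around
    library-size-scaled means.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = [f"miR-{i:04d}" for i in range(cfg.n_mirnas)]
    base = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_mirnas)
    prop = base / base.sum()

    half = 2.0 ** (cfg.de_log2fc / 2.0)
    # eligibility: expected counts comfortably above a 50-read floor even
    # after the down-shifted group's 2^(-fc/2) factor, and no single species
    # holding more than 5% of the library
    min_prop = 200.0 * max(half, 1.0 / half) / cfg.library_size_mean
    eligible = np.flatnonzero((prop >= min_prop) & (prop <= 0.05))
    if cfg.n_de > len(eligible):
        raise ValueError(
            f"cannot plant {cfg.n_de} effects: only {len(eligible)} miRNAs are "
            "abundant enough at this library size"
        )
    de_idx = rng.choice(eligible, size=cfg.n_de, replace=False)

    factor = np.ones((cfg.n_mirnas, 2))
    factor[de_idx, 0] = half
    factor[de_idx, 1] = 1.0 / half
    q_share = prop[de_idx].sum()
    for g, f in enumerate((half, 1.0 / half)):
        scale = (1.0 - q_share * f) / (1.0 - q_share) if q_share < 1.0 else -1.0
        if scale <= 0:
            raise ValueError(
                "planted miRNAs hold too large a share of the library to "
                "compensate; plant fewer or weaker effects"
            )
        unplanted = np.setdiff1d(np.arange(cfg.n_mirnas), de_idx)
        factor[unplanted, g] = scale

    n1, n2 = cfg.n_per_group
    labels = [cfg.group_labels[0]] * n1 + [cfg.group_labels[1]] * n2
    sample_ids = [f"{g}_{i + 1}" for i, g in enumerate(labels)]
    lib_sigma = np.sqrt(np.log1p(cfg.library_size_cv**2))
    counts = np.empty((cfg.n_mirnas, n1 + n2), dtype=np.int64)
    for j, g in enumerate([0] * n1 + [1] * n2):
        lib = rng.lognormal(np.log(cfg.library_size_mean) - lib_sigma**2 / 2, lib_sigma)
        mu = lib * prop * factor[:, g]
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=sample_ids),
        groups=pd.Series(labels, index=sample_ids, name="group"),
    )
    truth = PlantedTruth(de_mirnas={ids[i]: cfg.de_log2fc for i in sorted(de_idx)})
    return cm, truth


# ---------------------------------------------------------------------------
# RIP-Chip arrays


@dataclass
class RipChipSimConfig:
    """Two-condition, two-fraction array simulator settings.

    ``target_ip_log2_effect`` is added to the log2 IP signal of planted
    target probes in the miRNA-high condition only; inverting a comparison is
    done by swapping which condition is treated as numerator downstream.
    """

    n_probes: int = 2000
    n_targets: int = 100
    target_ip_log2_effect: float = 2.0
    baseline_sd: float = 1.5  # log2 spread of probe baselines across the array
    replicate_sd: float = 0.15  # log2 measurement noise per sample
    frac_absent: float = 0.05
    frac_inconsistent: float = 0.05
    seed: int = 0
    n_replicates: int = 2
    condition_low: str = "ctrl"
    condition_high: str = "mir-high"
    baseline_log2_mean: float = 10.0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_targets < 0 or self.n_targets > self.n_probes:
            raise ValueError("need 0 <= n_targets <= n_probes")
        if self.target_ip_log2_effect < 0:
            raise ValueError(
                "target_ip_log2_effect must be >= 0; invert the comparison "
                "by swapping conditions downstream"
            )
        for f in (self.frac_absent, self.frac_inconsistent):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.baseline_sd <= 0 or self.replicate_sd < 0:
            raise ValueError("spreads must be positive")
        if self.n_replicates < 1:
            raise ValueError("need >=1 replicate")


def simulate_ripchip_dataset(cfg: RipChipSimConfig) -> tuple[ArrayDataset, PlantedTruth]:
    """Simulate a two-fraction array experiment with planted RISC targets.

    Probe baselines are log-normal; each sample adds independent log2
    measurement noise.  Planted targets receive +``target_ip_log2_effect``
    on the IP signal in the miRNA-high condition only, so their expected
    cross-condition IP/T fold change is 2^effect and everything else sits at
    1.  Absent detection flags are planted on the lowest-baseline probes
    (real detection calls fail on dim probes) and always in at least one
    sample; inconsistent probes get one replicate shifted >=2-fold.  Targets
    are planted on probes that are flagged present, duplicate-consistent,
    and expressed above the filter percentile, i.e. on probes a real screen
    could call at all.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    probe_ids = [f"probe_{i:05d}" for i in range(n)]
    baseline = cfg.baseline_log2_mean + rng.normal(0.0, cfg.baseline_sd, size=n)

    order = np.argsort(baseline)
    n_absent = int(round(cfg.frac_absent * n))
    absent_idx = set(order[:n_absent].tolist())
    n_incons = int(round(cfg.frac_inconsistent * n))
    incons_idx = set(rng.choice(n, size=n_incons, replace=False).tolist())

    floor = np.quantile(baseline, 0.30)
    eligible = [
        i
        for i in range(n)
        if baseline[i] >= floor and i not in absent_idx and i not in incons_idx
    ]
    if cfg.n_targets > len(eligible):
        raise ValueError(
            f"cannot plant {cfg.n_targets} targets on {len(eligible)} eligible probes"
        )
    target_idx = np.asarray(
        rng.choice(eligible, size=cfg.n_targets, replace=False), dtype=int
    )
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    sample_rows = []
    columns = {}
    for cond in (cfg.condition_low, cfg.condition_high):
        for frac in ("T", "IP"):
            for rep in range(1, cfg.n_replicates + 1):
                name = f"{cond}__{frac}__{rep}"
                log2sig = baseline + rng.normal(0.0, cfg.replicate_sd, size=n)
                if frac == "IP" and cond == cfg.condition_high:
                    log2sig = log2sig + cfg.target_ip_log2_effect * is_target
                columns[name] = log2sig
                sample_rows.append(
                    {"sample": name, "condition": cond, "fraction": frac,
                     "replicate": rep}
                )
    signal_log2 = pd.DataFrame(columns, index=probe_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample")

    # planted duplicate inconsistency: one replicate of one (condition,
    # fraction) group is raised 1.1 log2 units above the group's maximum, so
    # the realized duplicate ratio exceeds 2-fold by construction
    groups = [
        (c, f)
        for c in (cfg.condition_low, cfg.condition_high)
        for f in ("T", "IP")
    ]
    if cfg.n_replicates >= 2:
        for i in sorted(incons_idx):
            cond, frac = groups[rng.integers(len(groups))]
            rep = int(rng.integers(1, cfg.n_replicates + 1))
            cols = [f"{cond}__{frac}__{r}" for r in range(1, cfg.n_replicates + 1)]
            pid = probe_ids[i]
            group_max = signal_log2.loc[pid, cols].max()
            signal_log2.loc[pid, f"{cond}__{frac}__{rep}"] = group_max + 1.1

    present = pd.DataFrame(True, index=probe_ids, columns=signal_log2.columns)
    n_samples = signal_log2.shape[1]
    for i in sorted(absent_idx):
        k = 1 + rng.binomial(n_samples - 1, 0.3)
        cols = rng.choice(n_samples, size=k, replace=False)
        present.iloc[i, cols] = False

    ds = ArrayDataset(
        signal=2.0**signal_log2,
        present=present,
        samples=samples,
        probe_info=pd.DataFrame(
            {
                "gene": [f"gene_{i:05d}" for i in range(n)],
                "transcript": [f"tx_{i:05d}" for i in range(n)],
            },
            index=probe_ids,
        ),
    )
    truth = PlantedTruth(
        target_probes={
            probe_ids[i]: cfg.target_ip_log2_effect for i in sorted(target_idx)
        },
        absent_probes={probe_ids[i] for i in absent_idx},
        inconsistent_probes={probe_ids[i] for i in incons_idx},
    )
    return ds, truth


# ---------------------------------------------------------------------------
# transcripts with planted seed sites


@dataclass
class TranscriptomeSimConfig:
    """Random-transcript simulator with seed sites planted on request.

    Each entry of ``planted_sites`` is a (site_type, region) pair planted on
    its own transcript (request i goes to transcript i); region
    ``"noncoding"`` makes that transcript noncoding, and its site is
    recorded under 3UTR following the reporting convention.
    """

    n_transcripts: int = 20
    length_range: tuple[int, int] = (300, 1500)
    planted_sites: list[tuple[str, str]] = field(default_factory=list)
    gc_content: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 60:
            raise ValueError("transcripts must be at least 60 nt")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if len(self.planted_sites) > self.n_transcripts:
            raise ValueError("more planted sites than transcripts (one per transcript)")
        for st, region in self.planted_sites:
            if st not in SITE_TYPES:
                raise ValueError(f"unknown site type {st!r}")
            if region not in ("5UTR", "CDS", "3UTR", "noncoding"):
                raise ValueError(f"unknown region {region!r}")


def _region_bounds(t: TranscriptModel, region: str) -> tuple[int, int]:
    L = len(t.sequence)
    if region == "noncoding":
        return 0, L
    return {
        "5UTR": (0, t.cds_start),
        "CDS": (t.cds_start, t.cds_end),
        "3UTR": (t.cds_end, L),
    }[region]


def simulate_transcriptome(
    cfg: TranscriptomeSimConfig, mirna: MatureMiRNA
) -> tuple[dict[str, TranscriptModel], PlantedTruth]:
    """Generate random transcripts and write requested seed sites into them.

    Planted patterns are guarded against accidental promotion: a planted
    7mer-m8 is never followed by an A (which would make it an 8mer) and a
    planted 7mer-A1 is never preceded by the nucleotide completing the 8mer,
    so a hierarchical scan recovers every planted site with its planted type.
    """
    rng = np.random.default_rng(cfg.seed)
    patterns = seed_patterns(mirna)
    alphabet = np.array(list("ACGU"))
    probs = np.array(
        [
            (1 - cfg.gc_content) / 2,
            cfg.gc_content / 2,
            cfg.gc_content / 2,
            (1 - cfg.gc_content) / 2,
        ]
    )
    transcripts: dict[str, TranscriptModel] = {}
    planted: list[tuple[str, int, str, str]] = []
    for i in range(cfg.n_transcripts):
        tx_id = f"tx{i:04d}"
        request = cfg.planted_sites[i] if i < len(cfg.planted_sites) else None
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = rng.choice(alphabet, size=L, p=probs)
        noncoding = request is not None and request[1] == "noncoding"
        if noncoding:
            t = TranscriptModel(tx_id, f"gene{i:04d}", "".join(seq))
        else:
            cds_start = max(20, int(0.15 * L))
            cds_end = min(L - 20, cds_start + max(30, int(0.55 * L)))
            t = TranscriptModel(tx_id, f"gene{i:04d}", "".join(seq),
                                cds_start, cds_end)
        if request is not None:
            site_type, region = request
            pat = patterns.pattern(site_type)
            lo, hi = _region_bounds(t, region)
            if hi - lo < len(pat) + 2:
                raise ValueError(
                    f"region {region} of {tx_id} ({hi - lo} nt) too short for "
                    f"a {site_type} site"
                )
            pos = int(rng.integers(lo + 1, hi - len(pat)))
            seq[pos : pos + len(pat)] = list(pat)
            if site_type == "7mer-m8" and pos + 7 < L and seq[pos + 7] == "A":
                seq[pos + 7] = "C"  # would otherwise read as an 8mer
            if site_type == "7mer-A1" and pos > 0:
                completes = patterns.site_8mer[0]
                if seq[pos - 1] == completes:
                    seq[pos - 1] = "C" if completes != "C" else "G"
            rec_region = REGION_3UTR if region == "noncoding" else region
            planted.append((tx_id, pos, site_type, rec_region))
            t = TranscriptModel(tx_id, t.gene, "".join(seq), t.cds_start, t.cds_end)
        transcripts[tx_id] = t
    return transcripts, PlantedTruth(site_positions=planted)


# ---------------------------------------------------------------------------
# GFP competition assay


@dataclass
class GfpSimConfig:
    """Exponential GFP-competition trajectory simulator.

    Trajectories follow baseline x exp(slope * (day - baseline_day)) with a
    log-scale replicate random intercept and log-scale observation noise.
    ``slope_diffs`` maps each non-reference construct to the difference of
    its decay slope (per day) from the shared control slope.  Defaults mimic
    an 18-day triplicate assay read three times a week from day 4.
    """

    slope_diffs: dict[str, float] = field(default_factory=lambda: {"mzip-mir": -0.12})
    reference_construct: str = "scr"
    control_slope: float = -0.01
    days: tuple[int, ...] = (4, 7, 9, 11, 14, 16, 18)
    n_replicates: int = 3
    baseline_pct: float = 40.0
    replicate_intercept_sd: float = 0.05
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.days) < 2:
            raise ValueError("need >=2 timepoints (mixed model unidentifiable)")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per construct")
        if not 0 < self.baseline_pct <= 100:
            raise ValueError("baseline_pct must lie in (0, 100]")


def simulate_gfp_assay(cfg: GfpSimConfig):
    """Simulate %GFP-positive trajectories for all constructs.

    Returns (series list, truth); truth records each non-reference
    construct's planted slope difference.
    """
    from .assays import GfpSeries  # local import to avoid cycle at module load

    rng = np.random.default_rng(cfg.seed)
    day0 = cfg.days[0]
    t = np.asarray(cfg.days, dtype=float) - day0
    series: list[GfpSeries] = []
    constructs = [(cfg.reference_construct, 0.0)] + sorted(cfg.slope_diffs.items())
    for name, diff in constructs:
        slope = cfg.control_slope + diff
        for rep in range(1, cfg.n_replicates + 1):
            u = rng.normal(0.0, cfg.replicate_intercept_sd)
            eps = rng.normal(0.0, cfg.noise_sd, size=len(t))
            pct = cfg.baseline_pct * np.exp(slope * t + u + eps)
            pct = np.clip(pct, 1e-3, 100.0)
            series.append(GfpSeries(name, f"rep{rep}", np.asarray(cfg.days, float), pct))
    return series, PlantedTruth(gfp_slope_diff=dict(cfg.slope_diffs))


# ---------------------------------------------------------------------------
# luciferase reporter assay


@dataclass
class LuciferaseSimConfig:
    """Dual-luciferase simulator: duplicate wells, paired biological replicates.

    ``suppression`` multiplies the Renilla signal in the experimental
    (mimic + wildtype site) arm only; 1.0 means no targeting.
    """

    n_replicates: int = 3
    suppression: float = 0.5
    rl_mean: float = 1000.0
    fl_mean: float = 2000.0
    replicate_sd: float = 0.1  # log-scale biological replicate effect
    duplicate_cv: float = 0.05  # technical well-to-well variation
    experimental_arm: str = "mimic"
    control_arm: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >=2 biological replicates")
        if self.suppression <= 0:
            raise ValueError("suppression must be positive")


def simulate_luciferase(cfg: LuciferaseSimConfig) -> pd.DataFrame:
    """Simulate duplicate (RL, FL) well readings for two paired arms.

    Returns a long DataFrame with columns replicate, arm, well, RL, FL.
    Replicate-level efficiency affects both arms of a pair (they are
    transfected from the same batch), which is what the paired analysis
    exploits.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        batch = np.exp(rng.normal(0.0, cfg.replicate_sd))
        for arm in (cfg.control_arm, cfg.experimental_arm):
            rl_scale = cfg.suppression if arm == cfg.experimental_arm else 1.0
            for well in (1, 2):
                noise = rng.normal(1.0, cfg.duplicate_cv, size=2)
                rows.append(
                    {
                        "replicate": f"rep{rep}",
                        "arm": arm,
                        "well": well,
                        "RL": cfg.rl_mean * rl_scale * batch * max(noise[0], 1e-6),
                        "FL": cfg.fl_mean * batch * max(noise[1], 1e-6),
                    }
                )
    return pd.DataFrame(rows)
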