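"""Readers and writers for the package's plain-text interchange formats.

Count matrices, two-fraction array datasets, transcript sets and assay
tables all travel as TSV; transcript sequences as FASTA (via Biopython);
planted truth as JSON.  Array sample columns are named
``<condition>__<fraction>__<replicate>``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ripchip import ArrayDataset
from .seedscan import TranscriptModel
from .smallrna import CountMatrix
from .synthetic import PlantedTruth

NONCODING_FLAG = "NC"


# -- count matrices ---------------------------------------------------------

def write_count_matrix(cm: CountMatrix, counts_path, groups_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="mirna")
    cm.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def read_count_matrix(counts_path, groups_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="mirna")
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
    return CountMatrix(counts=counts, groups=groups)


# -- array datasets ---------------------------------------------------------

def _parse_sample_columns(columns) -> pd.DataFrame:
    rows = []
    for c in columns:
        parts = c.split("__")
        if len(parts) != 3:
            raise ValueError(
                f"sample column {c!r} is not of the form condition__fraction__replicate"
            )
        rows.append(
            {"sample": c, "condition": parts[0], "fraction": parts[1],
             "replicate": int(parts[2])}
        )
    return pd.DataFrame(rows).set_index("sample")


def write_array_dataset(ds: ArrayDataset, signals_path, flags_path,
                        probes_path=None) -> None:
    ds.signal.to_csv(signals_path, sep="\t", index_label="probe_id")
    ds.present.astype(int).to_csv(flags_path, sep="\t", index_label="probe_id")
    if probes_path is not None and ds.probe_info is not None:
        ds.probe_info.to_csv(probes_path, sep="\t", index_label="probe_id")


def read_array_dataset(signals_path, flags_path, probes_path=None) -> ArrayDataset:
    signal = pd.read_csv(signals_path, sep="\t", index_col="probe_id")
    present = pd.read_csv(flags_path, sep="\t", index_col="probe_id").astype(bool)
    probe_info = None
    if probes_path is not None:
        probe_info = pd.read_csv(probes_path, sep="\t", index_col="probe_id")
    return ArrayDataset(
        signal=signal,
        present=present,
        samples=_parse_sample_columns(signal.columns),
        probe_info=probe_info,
    )


# -- transcript sets --------------------------------------------------------

def write_transcripts(transcripts: dict[str, TranscriptModel],
                      fasta_path, regions_path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=t.gene)
        for t in transcripts.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for t in transcripts.values():
        rows.append(
            {
                "transcript": t.id,
                "gene": t.gene,
                "cds_start": NONCODING_FLAG if t.noncoding else t.cds_start,
                "cds_end": NONCODING_FLAG if t.noncoding else t.cds_end,
            }
        )
    pd.DataFrame(rows).to_csv(regions_path, sep="\t", index=False)


def read_transcripts(fasta_path, regions_path) -> dict[str, TranscriptModel]:
    regions = pd.read_csv(regions_path, sep="\t", dtype=str).set_index("transcript")
    out: dict[str, TranscriptModel] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in regions.index:
            raise ValueError(f"transcript {rec.id} missing from the region table")
        row = regions.loc[rec.id]
        if row["cds_start"] == NONCODING_FLAG:
            cds_start = cds_end = None
        else:
            cds_start, cds_end = int(row["cds_start"]), int(row["cds_end"])
        out[rec.id] = TranscriptModel(
            id=rec.id,
            gene=row.get("gene", rec.id),
            sequence=str(rec.seq),
            cds_start=cds_start,
            cds_end=cds_end,
        )
    return out


# -- planted truth ----------------------------------------------------------

def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "de_mirnas": truth.de_mirnas,
        "target_probes": truth.target_probes,
        "absent_probes": sorted(truth.absent_probes) if truth.absent_probes else None,
        "inconsistent_probes": (
            sorted(truth.inconsistent_probes) if truth.inconsistent_probes else None
        ),
        "site_positions": truth.site_positions,
        "gfp_slope_diff": truth.gfp_slope_diff,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        de_mirnas=payload.get("de_mirnas"),
        target_probes=payload.get("target_probes"),
        absent_probes=(
            set(payload["absent_probes"]) if payload.get("absent_probes") else None
        ),
        inconsistent_probes=(
            set(payload["inconsistent_probes"])
            if payload.get("inconsistent_probes")
            else None
        ),
        site_positions=(
            [tuple(x) for x in payload["site_positions"]]
            if payload.get("site_positions")
            else None
        ),
        gfp_slope_diff=payload.get("gfp_slope_diff"),
    )
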