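"""Readers and writers for the package's text dialects.

Count tables, clinical tables, mature annotations and manifests are plain
tab-separated text; sequences are FASTA (read/written through Biopython).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .nomenclature import MatureAnnotation

COUNT_KEY_COLUMNS = ["mirna", "offset5", "offset3"]
CLINICAL_COLUMNS = ["sample_id", "time_days", "event", "histology", "gender", "tissue"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: uppercase sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_mature_annotations(path: str | Path) -> list[MatureAnnotation]:
    """Read the mature-annotation table (precursor_id, mirna, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"precursor_id", "mirna", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mature annotation table missing columns: {sorted(missing)}")
    return [
        MatureAnnotation(r.precursor_id, r.mirna, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read an isomiR count TSV into a DataFrame indexed by (mirna, offset5, offset3).

    Columns are sample ids; values are raw read counts.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing key columns: {missing}")
    df = df.set_index(COUNT_KEY_COLUMNS)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate isomiR rows in count table, e.g. {dups}")
    return df


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.reset_index().to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV, indexed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df.set_index("sample_id")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.reset_index().to_csv(path, sep="\t", index=False)


def write_manifest(entries: dict, path: str | Path) -> None:
    """Write a flat key-value manifest, one ``key<TAB>value`` per line."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}\t{value}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("\t")
        out[key] = value
    return out


def load_mir455_fixture() -> tuple[str, str, MatureAnnotation]:
    """Load the shipped hsa-mir-455 hairpin fixture.

    The hairpin is a synthetic stand-in: its mature 5p arm is the authentic
    hsa-miR-455-5p sequence and the templated base following the mature 3' end
    is the U implied by the published 0|1 probe, but the flanks and 3p arm are
    constructed, not the miRBase MI0003513 record.

    Returns (precursor_id, precursor_sequence, mature annotation).
    """
    pkg = resources.files("isomirdiv.data")
    seqs = read_fasta(pkg / "hsa-mir-455_synthetic.fa")
    anns = read_mature_annotations(pkg / "hsa-mir-455_synthetic_mature.tsv")
    ann = anns[0]
    return ann.precursor_id, seqs[ann.precursor_id], ann
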