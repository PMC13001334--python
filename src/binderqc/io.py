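"""Plain-text readers/writers for the pipeline's interchange formats.

FASTA goes through Biopython; tables are TSV via pandas. Schemas:

- metadata.tsv: design_id, team, design_class, used_mpnn
- counts.tsv:   design_id, input, cd20pos_1..k, cd20neg_1..k
- ss.tsv:       design_id, ss (string over {H,E,C})
- features.tsv: design_id + feature columns (see seqfeats.FEATURE_SCHEMA)
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_metadata(designs, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "design_id": [d.design_id for d in designs],
            "team": [d.team for d in designs],
            "design_class": [d.design_class for d in designs],
            "used_mpnn": [d.used_mpnn for d in designs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"design_id": str})
    required = {"design_id", "team"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return df


def write_counts(counts, path: str | Path) -> None:
    counts.counts.to_csv(path, sep="\t")


def read_counts(path: str | Path):
    from binderqc.screen import CountMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix.from_frame(df)


def write_ss(ss: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"design_id": list(ss), "ss": list(ss.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_ss(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"design_id", "ss"} <= set(df.columns):
        raise ValueError("SS file must have columns design_id, ss")
    bad = df.loc[~df["ss"].str.fullmatch("[HEC]*"), "design_id"].tolist()
    if bad:
        raise ValueError(f"SS strings with symbols outside H/E/C: {bad[:5]}")
    return dict(zip(df["design_id"], df["ss"]))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
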