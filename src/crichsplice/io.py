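"""File-format plumbing: FASTA, GTF, BED, FASTQ and provenance-stamped TSV.

GTF is handled as 1-based inclusive on disk and converted to 0-based
half-open at the boundary; BED is 0-based half-open throughout. TSV outputs
carry ``#``-prefixed provenance header lines (tool version, config hash,
seed) that the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__

GTF_COLUMNS = [
    "seqname",
    "source",
    "feature",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attribute",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_gtf(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", header=False, index=False, columns=GTF_COLUMNS)


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read a 9-column GTF; coordinates stay 1-based inclusive in the frame."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GTF_COLUMNS,
        dtype={"start": int, "end": int},
    )
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    with open(path) as fh:
        return [(rid, seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: dict | None = None, seed: int | None = None) -> str:
    parts = [f"crichsplice v{__version__}"]
    if config is not None:
        parts.append(f"config_sha256={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " | ".join(parts)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a TSV with a provenance comment line above the header row."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
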