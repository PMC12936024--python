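"""Readers and writers for the package's exchange formats.

Tabular data is TSV (pandas), sequences are FASTA (Biopython, header =
gene symbol), volumes are NIfTI (nibabel; axis 0 is the slice/z axis and
voxel spacing lives in the header zooms), configuration is YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rg4 import RG4Profile, StructureSummary, Transcript


# -- transcripts -------------------------------------------------------------

def write_fasta(transcripts: Sequence[Transcript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_symbol, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_regions(transcripts: Sequence[Transcript], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": t.gene_symbol, "utr5_end": t.utr5[1], "cds_end": t.cds[1]}
            for t in transcripts
        ]
    ).to_csv(path, sep="\t", index=False)


def read_transcripts(fasta_path: str | Path, regions_path: str | Path) -> list[Transcript]:
    """Join a FASTA file with its region-boundary table into Transcript objects."""
    regions = pd.read_csv(regions_path, sep="\t").set_index("gene")
    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in regions.index:
            raise ValueError(f"no region boundaries for gene {rec.id!r}")
        row = regions.loc[rec.id]
        transcripts.append(
            Transcript.from_boundaries(rec.id, str(rec.seq), int(row["utr5_end"]), int(row["cds_end"]))
        )
    return transcripts


# -- counts / gene sets ------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))


def write_groups(group: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample": list(group), "group": list(group.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_set(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# -- volumes -----------------------------------------------------------------

def write_nifti(array: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Save a (z, y, x) array with spacing (dz, dy, dx) mm in the affine."""
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array).astype(np.int16), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), (float(zooms[0]), float(zooms[1]), float(zooms[2]))


# -- result tables -----------------------------------------------------------

def motifs_frame(profiles: Sequence[RG4Profile]) -> pd.DataFrame:
    rows = [
        {
            "gene": p.gene_symbol,
            "start": m.start,
            "end": m.end,
            "region": m.region,
            "layers": m.layers,
            "loops": ",".join(map(str, m.loop_lengths)),
            "representative_loop": m.representative_loop,
            "score": m.score,
        }
        for p in profiles
        for m in p.motifs
    ]
    return pd.DataFrame(
        rows, columns=["gene", "start", "end", "region", "layers", "loops",
                       "representative_loop", "score"],
    )


def summary_frames(summary: StructureSummary) -> dict[str, pd.DataFrame]:
    """One tidy frame per structural table (region / gene bins / layers / loops)."""

    def tidy(table: Mapping, key_name: str) -> pd.DataFrame:
        return pd.DataFrame(
            [{key_name: k, "count": c, "percent": pct} for k, (c, pct) in table.items()]
        )

    return {
        "regions": tidy(summary.region_table, "region"),
        "gene_bins": tidy(summary.gene_count_bins, "n_rg4"),
        "layers": tidy(summary.layer_table, "layers"),
        "loops": tidy(summary.loop_table, "loop_length"),
    }
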