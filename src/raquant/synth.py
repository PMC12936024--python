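"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consumer assumes, at
desk scale, with a recorded ground truth sufficient to score the consumer
without rerunning the generator:

* transcripts with four-tract rG4 motifs planted at known coordinates in
  known regions, on a background provably free of scannable motifs;
* negative-binomial count matrices (var = mu + alpha*mu^2) with planted
  fold changes on named genes;
* 3D bone volumes containing axis-aligned box or ellipsoidal erosion
  lesions of known count, volume and maximum diameters, plus optional
  single-slice decoys that the pathological-erosion filter must drop;
* predicted masks degraded from gold to a requested Dice coefficient.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lesions import LabelVolume
from .rg4 import Transcript

_NONG = np.array(list("ACT"))


@dataclass(frozen=True)
class TranscriptSpec:
    """Cohort layout for transcript generation.

    Defaults mirror an irDEG screen cohort: 67 genes of which 42 carry
    planted motifs.  Planted tracts are 4 Gs, loops are drawn from {A, U}
    only; every plant then scores >= 0.5 (worst case 64/124 = 0.516 at
    loops 5,5,5) while long-loop plants fall below the strict 0.6 sweep
    threshold, so positive sets are non-trivially nested.
    """

    n_genes: int = 67
    n_positive: int = 42
    utr5_len: int = 200
    cds_len: int = 900
    utr3_len: int = 500
    tract_len: int = 4
    loop_choices: tuple[int, ...] = (1, 2, 3, 4, 5)
    max_motifs_per_gene: int = 3
    region_weights: tuple[float, float, float] = (0.18, 0.37, 0.45)  # 5UTR, CDS, 3UTR


def _background(rng: np.random.Generator, length: int) -> list[str]:
    """G-depleted background with no G-run of length >= 3 and non-G edges."""
    if length <= 0:
        return []
    bases = rng.choice(list("ACGT"), size=length, p=[0.30, 0.25, 0.15, 0.30]).tolist()
    for i in range(2, length):
        if bases[i] == bases[i - 1] == bases[i - 2] == "G":
            bases[i] = str(rng.choice(_NONG))
    for edge in (0, length - 1):
        if bases[edge] == "G":
            bases[edge] = str(rng.choice(_NONG))
    return bases


def _plant(rng: np.random.Generator, spec: TranscriptSpec) -> tuple[str, list[int]]:
    loops = [int(rng.choice(spec.loop_choices)) for _ in range(3)]
    parts = []
    for i in range(4):
        parts.append("G" * spec.tract_len)
        if i < 3:
            parts.append("".join(rng.choice(["A", "T"], size=loops[i])))
    return "".join(parts), loops


def gen_transcripts(
    spec: TranscriptSpec = TranscriptSpec(), seed: int = 0
) -> tuple[list[Transcript], pd.DataFrame, pd.DataFrame]:
    """Generate a transcript cohort with planted motifs.

    Returns (transcripts, gene truth table, motif truth table).  The gene
    table records each gene's planted positivity; the motif table records
    each plant's region, coordinates, tract length and loop lengths.  The
    background cannot contain any four-tract chain with tracts >= 3, so a
    canonical scan detects exactly the plants.
    """
    if not 0 <= spec.n_positive <= spec.n_genes:
        raise ValueError("need 0 <= n_positive <= n_genes")
    rng = np.random.default_rng(seed)
    region_bounds = {
        "5UTR": (0, spec.utr5_len),
        "CDS": (spec.utr5_len, spec.utr5_len + spec.cds_len),
        "3UTR": (spec.utr5_len + spec.cds_len, spec.utr5_len + spec.cds_len + spec.utr3_len),
    }
    total_len = spec.utr5_len + spec.cds_len + spec.utr3_len
    transcripts: list[Transcript] = []
    gene_rows, motif_rows = [], []
    for gi in range(spec.n_genes):
        gene = f"GENE{gi + 1:04d}"
        planted = gi < spec.n_positive
        n_motifs = int(rng.integers(1, spec.max_motifs_per_gene + 1)) if planted else 0
        # reserve non-overlapping slots, separated by >= 25 nt of background
        slots: list[tuple[str, int, str, list[int]]] = []
        attempts = 0
        while len(slots) < n_motifs and attempts < 200:
            attempts += 1
            region = str(rng.choice(["5UTR", "CDS", "3UTR"], p=spec.region_weights))
            motif_seq, loops = _plant(rng, spec)
            lo, hi = region_bounds[region]
            if hi - lo < len(motif_seq) + 4:
                continue
            start = int(rng.integers(lo + 2, hi - len(motif_seq) - 2))
            if all(
                start + len(motif_seq) + 25 <= s or start >= s + len(m) + 25
                for _, s, m, _ in slots
            ):
                slots.append((region, start, motif_seq, loops))
        slots.sort(key=lambda t: t[1])
        seq = _background(rng, total_len)
        for region, start, motif_seq, loops in slots:
            seq[start : start + len(motif_seq)] = list(motif_seq)
            seq[start - 1] = "A"  # hard non-G flanks so truth coordinates are exact
            seq[start + len(motif_seq)] = "A"
            motif_rows.append(
                {
                    "gene": gene,
                    "region": region,
                    "start": start,
                    "end": start + len(motif_seq),
                    "tract_len": spec.tract_len,
                    "loops": ",".join(map(str, loops)),
                }
            )
        transcripts.append(
            Transcript.from_boundaries(
                gene, "".join(seq), spec.utr5_len, spec.utr5_len + spec.cds_len
            )
        )
        gene_rows.append({"gene": gene, "positive": bool(slots), "n_planted": len(slots)})
    return transcripts, pd.DataFrame(gene_rows), pd.DataFrame(motif_rows)


@dataclass(frozen=True)
class CountsSpec:
    """Negative-binomial count design: two groups, planted fold changes.

    ``planted`` maps gene name -> log2 fold change (AG over BG).  Unlisted
    genes are null.  Baseline means are log-uniform in [mean_lo, mean_hi].
    """

    n_genes: int = 2000
    n_per_group: int = 20
    nb_dispersion: float = 0.1
    mean_lo: float = 20.0
    mean_hi: float = 500.0
    planted: dict[str, float] = field(default_factory=dict)
    gene_names: tuple[str, ...] | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float, size) -> np.ndarray:
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def gen_counts(
    spec: CountsSpec = CountsSpec(), seed: int = 0
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Generate a gene x sample NB count matrix with group labels and truth.

    Returns (counts, group map, truth table with per-gene planted log2fc and
    direction).  AG means are the baseline scaled by 2**log2fc.
    """
    if spec.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes = list(spec.gene_names) if spec.gene_names else [
        f"GENE{i + 1:04d}" for i in range(spec.n_genes)
    ]
    if len(genes) != spec.n_genes:
        raise ValueError("gene_names length must equal n_genes")
    unknown = set(spec.planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside the gene universe: {sorted(unknown)[:5]}")
    base = np.exp(rng.uniform(np.log(spec.mean_lo), np.log(spec.mean_hi), size=spec.n_genes))
    lfc = np.array([spec.planted.get(g, 0.0) for g in genes])
    mean_bg = base
    mean_ag = base * 2.0**lfc
    n = spec.n_per_group
    ag = _nb_draw(rng, mean_ag[:, None], spec.nb_dispersion, (spec.n_genes, n))
    bg = _nb_draw(rng, mean_bg[:, None], spec.nb_dispersion, (spec.n_genes, n))
    samples = [f"AG{i + 1:02d}" for i in range(n)] + [f"BG{i + 1:02d}" for i in range(n)]
    counts = pd.DataFrame(np.hstack([ag, bg]), index=genes, columns=samples)
    counts.index.name = "gene"
    group = {s: ("AG" if s.startswith("AG") else "BG") for s in samples}
    truth = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": lfc,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        }
    )
    return counts, group, truth


@dataclass(frozen=True)
class VolumeSpec:
    """Bone phantom layout: a solid bone block with separated lesions inside.

    Lesion kind is 'box' (exact closed-form diameters) or 'ellipsoid'
    (diameters measured on the voxelisation).  ``n_decoys`` single-slice
    plants exercise the pathological-erosion filter.
    """

    shape: tuple[int, int, int] = (48, 56, 56)
    spacing: tuple[float, float, float] = (0.625, 0.625, 0.625)
    n_lesions: int = 4
    n_decoys: int = 0
    kind: str = "box"
    size_range: tuple[int, int] = (2, 6)  # voxels per axis; z >= 2 for real lesions
    bone_margin: int = 4


def _box_diameters(dims: tuple[int, int, int], spacing: tuple[float, float, float]):
    (nz, ny, nx), (dz, dy, dx) = dims, spacing
    axial = float(np.hypot((nx - 1) * dx, (ny - 1) * dy))
    vertical = float(
        max(np.hypot((nx - 1) * dx, (nz - 1) * dz), np.hypot((ny - 1) * dy, (nz - 1) * dz))
    )
    return axial, vertical, max(axial, vertical)


def _brute_diameters(voxels: np.ndarray, spacing: tuple[float, float, float]):
    """Independent all-pairs diameter measurement for non-box truth."""
    dz, dy, dx = spacing
    mm = voxels * np.array([dz, dy, dx])
    axial = vertical = 0.0
    for i in range(len(voxels)):
        for j in range(i + 1, len(voxels)):
            d = mm[i] - mm[j]
            dist = float(np.sqrt((d**2).sum()))
            if voxels[i, 0] == voxels[j, 0]:
                axial = max(axial, dist)
            if voxels[i, 1] == voxels[j, 1] or voxels[i, 2] == voxels[j, 2]:
                vertical = max(vertical, dist)
    return axial, vertical, max(axial, vertical)


def gen_volume(
    spec: VolumeSpec = VolumeSpec(), seed: int = 0
) -> tuple[LabelVolume, pd.DataFrame]:
    """Generate a gold label volume, bone mask and per-lesion truth table.

    Lesions are pairwise separated by more than one voxel so they remain
    distinct components under 26-connectivity.  Truth rows carry voxel
    count, volume in mm^3, the analytic maximum diameters and a decoy flag
    (decoys span a single slice and must be dropped by the filter).
    """
    rng = np.random.default_rng(seed)
    dz, dy, dx = spec.spacing
    array = np.zeros(spec.shape, dtype=np.int16)
    bone = np.zeros(spec.shape, dtype=np.int16)
    m = spec.bone_margin
    bone[m:-m, m:-m, m:-m] = 1
    placed: list[tuple[np.ndarray, np.ndarray]] = []  # (lo, hi) inclusive bounding boxes
    rows = []
    total = spec.n_lesions + spec.n_decoys
    for li in range(total):
        decoy = li >= spec.n_lesions
        for _ in range(500):
            dims = rng.integers(spec.size_range[0], spec.size_range[1] + 1, size=3)
            if decoy:
                dims[0] = 1
            elif dims[0] < 2:
                dims[0] = 2
            lo = np.array(
                [int(rng.integers(m + 1, s - m - d - 1)) for s, d in zip(spec.shape, dims)]
            )
            hi = lo + dims - 1
            if all(np.any(hi + 2 < plo) or np.any(lo > phi + 2) for plo, phi in placed):
                placed.append((lo, hi))
                break
        else:
            raise RuntimeError("could not place lesions with the required separation")
        if spec.kind == "box":
            array[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = 1
            n_vox = int(np.prod(dims))
            axial, vertical, diam = _box_diameters(tuple(dims), spec.spacing)
        elif spec.kind == "ellipsoid":
            center = (lo + hi) / 2.0
            semi = np.maximum((hi - lo) / 2.0, 0.5)
            zz, yy, xx = np.meshgrid(
                *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
            )
            inside = (
                ((zz - center[0]) / semi[0]) ** 2
                + ((yy - center[1]) / semi[1]) ** 2
                + ((xx - center[2]) / semi[2]) ** 2
            ) <= 1.0
            vox = np.stack([zz[inside], yy[inside], xx[inside]], axis=1)
            array[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
            n_vox = len(vox)
            axial, vertical, diam = _brute_diameters(vox, spec.spacing)
        else:
            raise ValueError("kind must be 'box' or 'ellipsoid'")
        rows.append(
            {
                "lesion": li,
                "decoy": decoy,
                "min_z": int(lo[0]),
                "min_y": int(lo[1]),
                "min_x": int(lo[2]),
                "n_voxels": n_vox,
                "volume_mm3": n_vox * dz * dy * dx,
                "max_diam_axial_mm": axial,
                "max_diam_vertical_mm": vertical,
                "max_diam_mm": diam,
            }
        )
    bone |= array.astype(bone.dtype)  # erosions are part of the joint bone envelope
    truth = pd.DataFrame(rows).sort_values(["min_z", "min_y", "min_x"]).reset_index(drop=True)
    return LabelVolume(array=array, spacing=spec.spacing, bone_mask=bone), truth


def perturb_mask(gold: np.ndarray, target_dsc: float, seed: int) -> tuple[np.ndarray, float]:
    """Degrade a gold mask to a requested Dice coefficient.

    Removes r random gold voxels and adds r random background voxels
    adjacent to the gold surface, with r chosen so the resulting Dice
    2(G-r)/(2G) = 1 - r/G matches ``target_dsc``; the achieved value is
    returned and lands within 1/G of the request.  target 1.0 returns the
    gold mask unchanged.
    """
    if not 0.0 < target_dsc <= 1.0:
        raise ValueError("target_dsc must lie in (0, 1]")
    gold = np.asarray(gold).astype(bool)
    g = int(gold.sum())
    if g == 0:
        raise ValueError("gold mask is empty")
    r = int(round(g * (1.0 - target_dsc)))
    pred = gold.copy()
    if r == 0:
        return pred, 1.0
    rng = np.random.default_rng(seed)
    gold_idx = np.argwhere(gold)
    drop = gold_idx[rng.choice(g, size=r, replace=False)]
    pred[tuple(drop.T)] = False

    from scipy import ndimage

    shell = ndimage.binary_dilation(gold, iterations=1) & ~gold
    add_pool = np.argwhere(shell)
    extra = 2
    while len(add_pool) < r:
        shell = ndimage.binary_dilation(gold, iterations=extra) & ~gold
        add_pool = np.argwhere(shell)
        extra += 1
    add = add_pool[rng.choice(len(add_pool), size=r, replace=False)]
    pred[tuple(add.T)] = True
    tp = int((pred & gold).sum())
    achieved = 2.0 * tp / (pred.sum() + g)
    return pred, float(achieved)
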