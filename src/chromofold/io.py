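"""Readers and writers for the external text formats.

Formats: dense whitespace/CSV matrices and 3-column triplet text for Hi-C,
BED for TAD intervals, CSV for FISH mean-distance matrices and for 3D
conformations, plus a minimal PDB-like pseudo-atom dialect for viewing
models in molecular graphics software.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    ContactMap,
    Conformation,
    FishDistanceMatrix,
    GenomicBin,
    InputError,
    TadSet,
)

__all__ = [
    "load_contact_map",
    "load_tads",
    "load_fish_matrix",
    "write_conformation",
    "read_conformation",
    "write_fish_matrix",
    "write_contact_map",
    "write_tads",
]


def _load_dense(path) -> np.ndarray:
    try:
        return np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        return np.loadtxt(path, ndmin=2)


def _load_triplet(path, n: int | None) -> np.ndarray:
    df = pd.read_csv(
        path, sep=None, engine="python", header=None, comment="#",
        names=["i", "j", "value"],
    )
    if df.isna().any().any():
        raise InputError(f"malformed triplet file {path}")
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    v = df["value"].to_numpy(dtype=float)
    if i.min(initial=0) < 0 or j.min(initial=0) < 0:
        raise InputError("triplet indices must be 0-based and nonnegative")
    dim = n if n is not None else int(max(i.max(), j.max())) + 1
    if i.max() >= dim or j.max() >= dim:
        raise InputError("triplet index exceeds matrix dimension")
    m = np.zeros((dim, dim))
    m[i, j] = v
    m[j, i] = v
    return m


def load_contact_map(path, format: str = "dense", bins: TadSet | None = None,
                     resolution=None) -> ContactMap:
    """Load a contact map; symmetrized by (M + Mᵀ)/2; rejects negatives."""
    if format == "dense":
        m = _load_dense(path)
    elif format == "triplet":
        m = _load_triplet(path, len(bins) if bins is not None else None)
    else:
        raise InputError(f"unknown contact map format {format!r}")
    if np.any(m < 0):
        raise InputError(f"negative contact entries in {path}")
    m = 0.5 * (m + m.T)
    return ContactMap(m, bins=bins, resolution=resolution)


def load_tads(path) -> TadSet:
    """Load TAD intervals from a 3+-column BED file (0-based half-open)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise InputError(f"BED file {path} needs at least 3 columns")
    rows = [
        (str(r[0]), int(r[1]), int(r[2]))
        for r in df.iloc[:, :3].itertuples(index=False)
    ]
    return TadSet(rows)


def load_fish_matrix(path) -> FishDistanceMatrix:
    """Load a FISH mean-distance CSV (square, header = TAD ordinals, µm)."""
    df = pd.read_csv(path, index_col=0)
    m = df.to_numpy(dtype=float)
    return FishDistanceMatrix(m)


_CONF_COLUMNS = ["ordinal", "chrom", "start", "end", "x", "y", "z", "tad"]


def write_conformation(conf: Conformation, path, format: str = "csv") -> None:
    """Write a conformation as CSV or as a PDB-like pseudo-atom file."""
    if format == "csv":
        _write_conformation_csv(conf, path)
    elif format == "pdb":
        _write_conformation_pdb(conf, path)
    else:
        raise InputError(f"unknown conformation format {format!r}")


def _write_conformation_csv(conf: Conformation, path) -> None:
    n = len(conf)
    if conf.bins is not None:
        chrom = [b.chrom for b in conf.bins]
        start = [b.start for b in conf.bins]
        end = [b.end for b in conf.bins]
    else:
        chrom, start, end = ["."] * n, [-1] * n, [-1] * n
    df = pd.DataFrame(
        {
            "ordinal": np.arange(n),
            "chrom": chrom,
            "start": start,
            "end": end,
            "x": conf.coords[:, 0],
            "y": conf.coords[:, 1],
            "z": conf.coords[:, 2],
            "tad": conf.tad_ids,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_conformation(path) -> Conformation:
    df = pd.read_csv(path)
    missing = [c for c in _CONF_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"conformation CSV {path} lacks columns {missing}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    bins = None
    if (df["start"] >= 0).all():
        bins = [
            GenomicBin(str(c), int(s), int(e), i)
            for i, (c, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"]))
        ]
    return Conformation(coords, bins=bins, tad_ids=df["tad"].to_numpy(dtype=int))


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


def _write_conformation_pdb(conf: Conformation, path) -> None:
    # One pseudo-atom per point, one chain per TAD, consecutive points bonded.
    # PDB coordinate fields are 8 characters; rescale if any |coord| >= 9999.
    coords = conf.coords
    span = np.abs(coords).max() if len(coords) else 0.0
    scale = 1.0
    if span >= 9999.0:
        scale = 999.0 / span
    lines = []
    lines.append("REMARK   3D chromosome model; pseudo-atoms, coordinates in um")
    lines.append(f"REMARK   coordinate scale factor applied: {scale:.6g}")
    for k, (x, y, z) in enumerate(coords * scale):
        chain = _CHAIN_IDS[int(conf.tad_ids[k]) % len(_CHAIN_IDS)]
        serial = (k + 1) % 100000
        resseq = (k + 1) % 10000
        lines.append(
            f"HETATM{serial:5d}  CA  BIN {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    for k in range(len(coords) - 1):
        lines.append(f"CONECT{(k + 1) % 100000:5d}{(k + 2) % 100000:5d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fish_matrix(fish: FishDistanceMatrix, path) -> None:
    m = fish.matrix.copy()
    m[fish.missing] = np.nan
    np.fill_diagonal(m, 0.0)
    labels = [str(i) for i in range(fish.n)]
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path, float_format="%.9g")


def write_contact_map(cmap: ContactMap, path) -> None:
    np.savetxt(path, cmap.matrix, delimiter=",", fmt="%.9g")


def write_tads(tads: TadSet, path) -> None:
    with open(path, "w") as fh:
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
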