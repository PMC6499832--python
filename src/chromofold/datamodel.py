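"""Core domain types for 3D chromosome modeling.

All spatial coordinates and distances are micrometres (µm); genomic
coordinates are 0-based half-open base-pair intervals (BED convention);
matrix indices are 0-based.  Hi-C contact values are unitless (raw or
pre-normalized counts are both accepted — the stochastic-neighbor
affinity used downstream is scale invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputError",
    "NumericalError",
    "GenomicBin",
    "TadSet",
    "ContactMap",
    "FishDistanceMatrix",
    "Conformation",
]


class InputError(ValueError):
    """Invalid or inconsistent user input (exit code 2 in the CLI)."""


class NumericalError(RuntimeError):
    """Numerical failure during optimization (exit code 3 in the CLI)."""


@dataclass(frozen=True)
class GenomicBin:
    """A genomic interval carrying its ordinal position in a model."""

    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    index: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(
                f"bin {self.index}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


class TadSet:
    """Ordered, non-overlapping TAD intervals on a single chromosome."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        intervals = sorted(intervals, key=lambda iv: (iv[0], iv[1]))
        chroms = {iv[0] for iv in intervals}
        if len(chroms) > 1:
            raise InputError(f"TADs span multiple chromosomes: {sorted(chroms)}")
        bins = []
        for i, (chrom, start, end) in enumerate(intervals):
            bins.append(GenomicBin(chrom, int(start), int(end), i))
            if i > 0 and start < intervals[i - 1][2]:
                raise InputError(
                    f"TADs overlap: {intervals[i - 1]} and {(chrom, start, end)}"
                )
        if not bins:
            raise InputError("empty TAD set")
        self.tads: list[GenomicBin] = bins

    def __len__(self) -> int:
        return len(self.tads)

    def __getitem__(self, i: int) -> GenomicBin:
        return self.tads[i]

    def __iter__(self):
        return iter(self.tads)

    @property
    def chrom(self) -> str:
        return self.tads[0].chrom

    def genomic_gap(self, i: int) -> int:
        """Gap g_{i,i+1} in bp between the end of TAD i and start of TAD i+1."""
        return self.tads[i + 1].start - self.tads[i].end

    def center_separation(self, i: int, j: int) -> float:
        """Center-to-center genomic distance in bp."""
        return abs(self.tads[j].center - self.tads[i].center)


def _check_square(matrix: np.ndarray, name: str) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InputError(f"{name} must be square, got shape {matrix.shape}")
    return matrix


class ContactMap:
    """Symmetric nonnegative contact-frequency matrix over bins or TADs."""

    def __init__(self, matrix: np.ndarray, bins=None, resolution=None):
        matrix = _check_square(matrix, "contact matrix")
        if np.any(matrix < 0):
            raise InputError("contact matrix has negative entries")
        if not np.all(np.isfinite(matrix)):
            raise InputError("contact matrix has non-finite entries")
        scale = max(np.abs(matrix).max(), 1.0)
        if np.abs(matrix - matrix.T).max() > 1e-9 * scale:
            matrix = 0.5 * (matrix + matrix.T)
        np.fill_diagonal(matrix, 0.0)
        if bins is not None and len(bins) != matrix.shape[0]:
            raise InputError(
                f"contact matrix is {matrix.shape[0]}x{matrix.shape[0]} but "
                f"{len(bins)} bins were given"
            )
        self.matrix = matrix
        self.bins = bins
        self.resolution = resolution

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


class FishDistanceMatrix:
    """Mean pairwise spatial distances between TADs (µm), with missing mask.

    ``missing[i, j]`` is True where no measurement exists; those entries are
    excluded from the FISH cost term and from relative-error averaging,
    never imputed.
    """

    def __init__(self, matrix: np.ndarray, missing: np.ndarray | None = None):
        matrix = _check_square(matrix, "FISH distance matrix")
        nan_mask = ~np.isfinite(matrix)
        if missing is None:
            missing = nan_mask
        else:
            missing = np.asarray(missing, dtype=bool) | nan_mask
        missing = missing | missing.T
        np.fill_diagonal(missing, True)
        scale = np.nanmax(np.abs(matrix)) if np.any(~nan_mask) else 1.0
        asym = np.nan_to_num(matrix - matrix.T, nan=0.0)
        if np.abs(asym).max() > 1e-9 * max(scale, 1.0):
            warnings.warn("asymmetric FISH matrix; symmetrizing by averaging")
        matrix = 0.5 * (np.nan_to_num(matrix, nan=0.0) + np.nan_to_num(matrix.T, nan=0.0))
        np.fill_diagonal(matrix, 0.0)
        if np.any(matrix[~missing] < 0):
            raise InputError("FISH distances must be nonnegative")
        self.matrix = matrix
        self.missing = missing

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of usable off-diagonal entries."""
        return ~self.missing

    def defined_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) index arrays of defined upper-triangle entries."""
        iu, ju = np.triu_indices(self.n, k=1)
        keep = self.defined[iu, ju]
        return iu[keep], ju[keep]


@dataclass
class Conformation:
    """Ordered 3D points (µm) with genomic/TAD metadata.

    ``tad_ids`` maps each point to a TAD ordinal; for a TAD-level backbone
    conformation it is simply ``arange(n)``.
    """

    coords: np.ndarray  # (n, 3)
    bins: list[GenomicBin] | None = None
    tad_ids: np.ndarray | None = None
    _tad_slices: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 3:
            raise InputError(f"coordinates must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        if self.bins is not None and len(self.bins) != len(self.coords):
            raise InputError("bin metadata length does not match point count")
        if self.tad_ids is None:
            self.tad_ids = np.arange(len(self.coords))
        else:
            self.tad_ids = np.asarray(self.tad_ids, dtype=int)
            if len(self.tad_ids) != len(self.coords):
                raise InputError("tad_ids length does not match point count")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_tads(self) -> int:
        return len(np.unique(self.tad_ids))

    def tad_slice(self, tad: int) -> slice:
        """Contiguous index slice of the points belonging to TAD ``tad``."""
        if tad not in self._tad_slices:
            idx = np.flatnonzero(self.tad_ids == tad)
            if idx.size == 0:
                raise InputError(f"no points belong to TAD {tad}")
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise InputError(f"points of TAD {tad} are not contiguous")
            self._tad_slices[tad] = slice(int(idx[0]), int(idx[-1]) + 1)
        return self._tad_slices[tad]

    def tad_first(self, tad: int) -> np.ndarray:
        """Coordinates y_{s_i} of the first point of TAD ``tad``."""
        return self.coords[self.tad_slice(tad).start]

    def tad_last(self, tad: int) -> np.ndarray:
        """Coordinates y_{e_i} of the last point of TAD ``tad``."""
        return self.coords[self.tad_slice(tad).stop - 1]

    def tad_centroid(self, tad: int) -> np.ndarray:
        return self.coords[self.tad_slice(tad)].mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        return Conformation(coords, bins=self.bins, tad_ids=self.tad_ids.copy())

    def copy(self) -> "Conformation":
        return self.with_coords(self.coords.copy())
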