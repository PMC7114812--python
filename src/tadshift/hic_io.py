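"""Contact-matrix input/output and basic preprocessing.

Hi-C contact maps are handled per chromosome as dense square matrices at a
fixed bin resolution (default 10 kb).  Two plain-text dialects are accepted:
a full tab-separated dense matrix (n lines of n numeric fields) and sparse
``bin_i  bin_j  value`` triples.  This module also implements vanilla
coverage normalization and binomial depth down-sampling, the two raw-matrix
transformations the rest of the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ContactMatrix",
    "BinInterval",
    "TAD",
    "TADSet",
    "FormatError",
    "ValidationError",
    "read_contact_matrix",
    "vanilla_coverage_normalize",
    "downsample_depth",
    "write_tads",
    "read_tads_bed",
    "write_scores",
]


class FormatError(ValueError):
    """Malformed input file (wrong shape, non-numeric fields, ...)."""


class ValidationError(ValueError):
    """Well-formed input that violates a semantic precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinInterval:
    """Half-open bin interval ``[left, right)``, 0-based."""

    left: int
    right: int

    def __post_init__(self) -> None:
        if not 0 <= self.left < self.right:
            raise ValidationError(
                f"invalid interval [{self.left}, {self.right})"
            )

    def __len__(self) -> int:
        return self.right - self.left

    def contains(self, other: "BinInterval") -> bool:
        return self.left <= other.left and other.right <= self.right

    def crosses(self, other: "BinInterval") -> bool:
        """True if the two intervals partially overlap (neither nested nor
        disjoint)."""
        a, b = (self, other) if self.left <= other.left else (other, self)
        return a.left < b.left < a.right < b.right


@dataclass(frozen=True)
class TAD:
    """A topologically associating domain with its pairing probability."""

    interval: BinInterval
    probability: float = 0.0

    def __post_init__(self) -> None:
        if self.probability < 0:
            raise ValidationError("TAD probability must be >= 0")


@dataclass
class TADSet:
    """Per-chromosome TAD calls, sorted by left boundary.

    Nesting is allowed (hierarchical domains); partial overlap between two
    members ("crossing") is not.
    """

    tads: list[TAD] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tads = sorted(
            self.tads, key=lambda t: (t.interval.left, t.interval.right)
        )
        for i, a in enumerate(self.tads):
            for b in self.tads[i + 1 :]:
                if b.interval.left >= a.interval.right:
                    break
                if a.interval.crosses(b.interval):
                    raise ValidationError(
                        f"crossing TADs {a.interval} / {b.interval}"
                    )

    def __len__(self) -> int:
        return len(self.tads)

    def __iter__(self):
        return iter(self.tads)

    def intervals(self) -> list[BinInterval]:
        return [t.interval for t in self.tads]


@dataclass
class ContactMatrix:
    """Square symmetric-by-construction Hi-C contact map for one chromosome.

    Parameters
    ----------
    values
        ``n x n`` non-negative matrix of contact frequencies.  Raw matrices
        hold integer read counts; normalized matrices hold real frequencies
        and need not be symmetric (vanilla coverage normalization is applied
        row-first and breaks exact symmetry).
    bin_size
        Genomic width of one bin in base pairs.
    chrom
        Chromosome label carried through to BED output.
    start_coord
        Genomic coordinate (bp, 0-based) of the left edge of bin 0.
    normalized
        ``"raw"`` or ``"vanilla-coverage"``.
    """

    values: np.ndarray
    bin_size: int = 10_000
    chrom: str = "chr1"
    start_coord: int = 0
    normalized: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"contact matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("contact matrix contains NaN/inf")
        if np.any(v < 0):
            raise ValidationError("contact matrix contains negative values")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_to_bp(self, bin_index: int) -> int:
        return self.start_coord + bin_index * self.bin_size


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_contact_matrix(
    path: str | Path,
    format: str = "dense-tsv",
    bin_size: int = 10_000,
    chrom: str = "chr1",
    start_coord: int = 0,
) -> ContactMatrix:
    """Read a per-chromosome contact matrix.

    ``format="dense-tsv"`` expects n lines of n tab-separated numeric
    fields; ``format="sparse-triples"`` expects lines of
    ``bin_i<TAB>bin_j<TAB>value`` which are mirrored into a symmetric dense
    matrix (missing cells are 0).  Conflicting duplicate entries for a
    mirrored pair raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense-tsv":
        try:
            values = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:  # ragged rows / non-numeric fields
            raise FormatError(f"cannot parse dense matrix {path}: {exc}") from exc
        if values.size == 0:
            raise FormatError(f"empty matrix file {path}")
        if values.shape[0] != values.shape[1]:
            raise FormatError(
                f"dense matrix must be square, got {values.shape}"
            )
    elif format == "sparse-triples":
        try:
            trip = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse triples {path}: {exc}") from exc
        if trip.size == 0:
            raise FormatError(f"empty triples file {path}")
        if trip.shape[1] != 3:
            raise FormatError("sparse triples need exactly 3 columns")
        ii = trip[:, 0].astype(int)
        jj = trip[:, 1].astype(int)
        vv = trip[:, 2]
        if np.any(ii < 0) or np.any(jj < 0):
            raise ValidationError("negative bin index in triples")
        n = int(max(ii.max(), jj.max())) + 1
        values = np.zeros((n, n))
        seen = np.zeros((n, n), dtype=bool)
        for i, j, v in zip(ii, jj, vv):
            a, b = (i, j) if i <= j else (j, i)
            if seen[a, b] and values[a, b] != v:
                raise ValidationError(
                    f"conflicting duplicate entries for bin pair ({i},{j})"
                )
            seen[a, b] = True
            values[a, b] = v
            values[b, a] = v
    else:
        raise ValueError(f"unknown format {format!r}")
    return ContactMatrix(
        values, bin_size=bin_size, chrom=chrom, start_coord=start_coord
    )


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def vanilla_coverage_normalize(m: ContactMatrix) -> ContactMatrix:
    """Vanilla coverage normalization, row step then column step.

    Every element is divided by its row sum, then by the column sum of the
    row-normalized matrix.  Zero-sum rows/columns are passed through
    untouched at the corresponding step so bin indexing is preserved.  The
    result is generally not symmetric; downstream code never requires
    symmetry.
    """
    v = m.values
    if not np.any(v > 0):
        raise ValidationError("cannot normalize an all-zero matrix")
    rowsum = v.sum(axis=1)
    safe_row = np.where(rowsum > 0, rowsum, 1.0)
    out = v / safe_row[:, None]
    colsum = out.sum(axis=0)
    safe_col = np.where(colsum > 0, colsum, 1.0)
    out = out / safe_col[None, :]
    return replace(m, values=out, normalized="vanilla-coverage")


def downsample_depth(
    m: ContactMatrix, target_total: int, seed: int
) -> ContactMatrix:
    """Thin raw integer counts to a lower sequencing depth.

    Each upper-triangle (incl. diagonal) count is replaced by an independent
    ``Binomial(count, p)`` draw with ``p = target_total / current_total``
    and mirrored, so the expected total equals ``target_total``.
    """
    v = m.values
    if m.normalized != "raw" or not np.allclose(v, np.round(v)):
        raise ValidationError("depth down-sampling requires raw integer counts")
    counts = np.round(v).astype(np.int64)
    iu = np.triu_indices(m.n_bins)
    total = int(counts[iu].sum())
    if target_total > total:
        raise ValidationError(
            f"target depth {target_total} exceeds current total {total}"
        )
    p = target_total / total
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(counts[iu], p)
    out = np.zeros_like(counts)
    out[iu] = thinned
    out = out + np.triu(out, 1).T
    return replace(m, values=out.astype(float))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_tads(
    tads: TADSet,
    path: str | Path,
    chrom: str = "chr1",
    bin_size: int = 10_000,
    start_coord: int = 0,
    probabilities: bool = True,
) -> None:
    """Write TAD calls as BED3 (+ optional probability column).

    Coordinates are 0-based half-open:
    ``start_bp = start_coord + left * bin_size``.
    """
    path = Path(path)
    with path.open("w") as fh:
        if probabilities:
            fh.write("#chrom\tstart\tend\tprobability\n")
        for t in tads:
            start = start_coord + t.interval.left * bin_size
            end = start_coord + t.interval.right * bin_size
            if probabilities:
                fh.write(f"{chrom}\t{start}\t{end}\t{t.probability:.6g}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_tads_bed(
    path: str | Path, bin_size: int = 10_000, start_coord: int = 0
) -> TADSet:
    """Read BED TAD calls back into bin coordinates (inverse of
    :func:`write_tads`; also accepts calls from external TAD callers)."""
    tads = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"bad BED line: {line!r}")
        start, end = int(parts[1]), int(parts[2])
        prob = float(parts[3]) if len(parts) > 3 else 0.0
        left = (start - start_coord) // bin_size
        right = (end - start_coord) // bin_size
        tads.append(TAD(BinInterval(left, right), prob))
    return TADSet(tads)


def write_scores(records: Sequence, path: str | Path) -> None:
    """Write split/merger score records as a TSV with header.

    ``records`` are :class:`tadshift.split_merge.SplitScoreRecord`; the
    import is deferred to keep module dependencies one-directional.
    """
    path = Path(path)
    cols = [
        "chrom", "big_start", "big_end", "chain", "chain_probability",
        "csr", "scc", "lms", "ihs", "direction", "called", "split_sites",
    ]
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            iv = r.match.big_tad.interval
            chain = ";".join(
                f"{c.left}-{c.right}" for c in r.match.chain_intervals()
            )
            sites = ";".join(str(s) for s in r.split_sites_bp)
            fmt = lambda x: "NA" if x is None else f"{x:.6g}"
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.big_start_bp),
                        str(r.big_end_bp),
                        chain,
                        f"{r.match.chain_probability:.6g}",
                        f"{r.csr:.6g}",
                        fmt(r.scc),
                        fmt(r.lms),
                        fmt(r.ihs),
                        r.direction,
                        str(int(r.called)),
                        sites,
                    ]
                )
                + "\n"
            )
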