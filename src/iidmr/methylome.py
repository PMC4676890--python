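"""Multi-individual per-CpG methylation count data.

The central container is :class:`MethylomeSet`: for each CpG dinucleotide
(keyed to the 0-based position of the C on the forward strand) it holds a
(methylated, total) read-count pair per individual, genome-ordered.  Counts
arrive as Bismark-style cytosine reports (one file per individual, 1-based,
strand-resolved); the two strands of a CpG are merged into a single count
pair before analysis.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylomeSet",
    "WindowSummary",
    "read_cytosine_report",
    "write_cytosine_report",
    "merge_strands",
    "coverage_filter",
    "coverage_histogram",
    "window_methylation",
    "write_methylome_tsv",
    "read_methylome_tsv",
]

_REPORT_COLUMNS = ["chrom", "pos1", "strand", "meth", "unmeth", "context"]


class CytosineReportError(ValueError):
    """Raised for malformed cytosine-report input."""


@dataclass
class MethylomeSet:
    """Genome-ordered per-CpG counts for a fixed panel of individuals.

    Parameters
    ----------
    individuals
        Ordered individual identifiers; the column order of ``meth``/``total``.
    chrom
        Chromosome name per site, shape ``(n_sites,)``.
    pos
        0-based forward-strand C position per site, shape ``(n_sites,)``.
    meth, total
        Integer count matrices of shape ``(n_sites, n_individuals)`` with
        ``0 <= meth <= total`` elementwise.
    labels
        Optional free-form per-individual labels (e.g. coat colour).
    """

    individuals: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.atleast_2d(np.asarray(self.meth, dtype=np.int64))
        self.total = np.atleast_2d(np.asarray(self.total, dtype=np.int64))
        n = len(self.pos)
        k = len(self.individuals)
        if self.meth.shape != (n, k) or self.total.shape != (n, k):
            raise ValueError(
                f"count matrices must be (n_sites={n}, n_individuals={k}); "
                f"got meth {self.meth.shape}, total {self.total.shape}"
            )
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValueError("negative counts")
        if np.any(self.meth > self.total):
            raise ValueError("methylated count exceeds total count")
        self._sort_and_check()

    def _sort_and_check(self) -> None:
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.meth = self.meth[order]
            self.total = self.total[order]
        if len(self.pos) > 1:
            same = self.chrom[1:] == self.chrom[:-1]
            if np.any(same & (self.pos[1:] == self.pos[:-1])):
                raise ValueError("duplicate (chrom, pos) site")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def indices_of(self, individuals: list[str]) -> np.ndarray:
        try:
            return np.array([self.individuals.index(i) for i in individuals])
        except ValueError as exc:
            raise KeyError(f"unknown individual: {exc}") from None

    def subset_sites(self, keep: np.ndarray) -> "MethylomeSet":
        """New set containing the sites selected by boolean/index array."""
        return MethylomeSet(
            individuals=list(self.individuals),
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            meth=self.meth[keep],
            total=self.total[keep],
            labels=dict(self.labels),
        )

    @classmethod
    def from_site_tables(
        cls,
        tables: dict[str, pd.DataFrame],
        labels: dict[str, str] | None = None,
    ) -> "MethylomeSet":
        """Assemble a set from per-individual merged site tables.

        Each table must carry columns ``chrom, pos, meth, total`` (0-based,
        strand-merged, one row per CpG).  Sites are outer-joined across
        individuals; an individual without data at a site gets (0, 0).
        """
        individuals = list(tables)
        frames = []
        for ind, tab in tables.items():
            t = tab[["chrom", "pos", "meth", "total"]].copy()
            t = t.set_index(["chrom", "pos"])
            t.columns = pd.MultiIndex.from_product([[ind], ["meth", "total"]])
            frames.append(t)
        wide = pd.concat(frames, axis=1).fillna(0).astype(np.int64).sort_index()
        meth = np.column_stack([wide[(i, "meth")].to_numpy() for i in individuals])
        total = np.column_stack([wide[(i, "total")].to_numpy() for i in individuals])
        idx = wide.index.to_frame(index=False)
        return cls(
            individuals=individuals,
            chrom=idx["chrom"].to_numpy(dtype=object),
            pos=idx["pos"].to_numpy(dtype=np.int64),
            meth=meth,
            total=total,
            labels=labels or {},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: chrom, pos, then meth/total per individual."""
        data: dict[str, np.ndarray] = {"chrom": self.chrom, "pos": self.pos}
        for j, ind in enumerate(self.individuals):
            data[f"{ind}.meth"] = self.meth[:, j]
            data[f"{ind}.total"] = self.total[:, j]
        return pd.DataFrame(data)


@dataclass
class WindowSummary:
    """Fixed-width genomic window with per-individual weighted methylation.

    ``methylation`` entries are NaN where a window has no informative CpG
    coverage for that individual (missing, never 0).
    """

    chrom: str
    start: int
    end: int
    methylation: np.ndarray  # (n_individuals,) float, NaN = missing
    n_informative_cpgs: int


def _open_maybe_gzip(path, mode="rt"):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    return open(p, mode)


def read_cytosine_report(path, individual_id: str | None = None) -> pd.DataFrame:
    """Read one individual's cytosine report into a strand-resolved table.

    The report is TSV with columns chrom, 1-based position, strand (+/-),
    methylated count, unmethylated count, context; only ``CG`` rows are
    used.  Returns a frame with columns ``chrom, pos, strand, meth, total``
    where ``pos`` is 0-based.  Row order is preserved as read (sorting is a
    downstream concern).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
            },
            comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise CytosineReportError(f"{path}: malformed cytosine report: {exc}") from exc
    for col in ("pos1", "meth", "unmeth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise CytosineReportError(
                f"{path}: non-numeric value in column '{col}' at line {line}"
            )
        df[col] = converted
    if df[["pos1", "meth", "unmeth"]].isna().any().any():
        line = int(df[["pos1", "meth", "unmeth"]].isna().any(axis=1).idxmax()) + 1
        raise CytosineReportError(f"{path}: missing field at line {line}")
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        line = int(((df["meth"] < 0) | (df["unmeth"] < 0)).idxmax()) + 1
        raise CytosineReportError(f"{path}: negative count at line {line}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise CytosineReportError(f"{path}: invalid strand at line {line}")
    df = df[df["context"] == "CG"].copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos1"].astype(np.int64).to_numpy() - 1,
            "strand": df["strand"].to_numpy(),
            "meth": df["meth"].astype(np.int64).to_numpy(),
            "total": (df["meth"] + df["unmeth"]).astype(np.int64).to_numpy(),
        }
    )
    if individual_id is not None:
        out.attrs["individual_id"] = individual_id
    return out.reset_index(drop=True)


def write_cytosine_report(table: pd.DataFrame, path) -> None:
    """Write a strand-resolved site table back to cytosine-report TSV.

    Inverse of :func:`read_cytosine_report` for CG rows (positions
    re-converted to 1-based, total split back into unmethylated counts).
    """
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos1": table["pos"].astype(np.int64) + 1,
            "strand": table["strand"],
            "meth": table["meth"].astype(np.int64),
            "unmeth": (table["total"] - table["meth"]).astype(np.int64),
            "context": "CG",
        }
    )
    with _open_maybe_gzip(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def merge_strands(table: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each CpG into one count pair.

    A forward-strand record at position ``p`` pairs with a reverse-strand
    record at ``p + 1`` on the same chromosome; counts are summed and the
    merged site is keyed to ``p`` (the forward-strand C).  Unpaired records
    are kept: an unpaired reverse record is keyed to ``p - 1`` so all output
    positions refer to the forward-strand C of the dinucleotide.

    Returns a frame with columns ``chrom, pos, meth, total`` sorted by
    (chrom, pos).
    """
    fwd = table["strand"] == "+"
    key_pos = np.where(fwd, table["pos"], table["pos"] - 1)
    merged = (
        pd.DataFrame(
            {
                "chrom": table["chrom"],
                "pos": key_pos,
                "meth": table["meth"],
                "total": table["total"],
            }
        )
        .groupby(["chrom", "pos"], as_index=False, sort=True)
        .sum()
    )
    return merged


def coverage_filter(
    mset: MethylomeSet,
    min_coverage: int,
    included_individuals: list[str] | None = None,
    mode: str = "all",
) -> MethylomeSet:
    """Retain sites adequately covered in the individuals used for calling.

    With ``mode="all"`` (default) a site is kept only when *every* included
    individual has ``total >= min_coverage`` — the heterogeneity test and
    weighted averages need counts from every compared individual.  With
    ``mode="any"`` a site is kept when at least one included individual
    meets the threshold (per-individual missingness handled downstream).
    The input set is not modified.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if included_individuals is None:
        included_individuals = list(mset.individuals)
    if not included_individuals:
        raise ValueError("included_individuals must be non-empty")
    cols = mset.indices_of(included_individuals)
    cov_ok = mset.total[:, cols] >= min_coverage
    if mode == "all":
        keep = cov_ok.all(axis=1)
    elif mode == "any":
        keep = cov_ok.any(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return mset.subset_sites(keep)


def coverage_histogram(
    mset: MethylomeSet, bin_edges: list[float]
) -> pd.DataFrame:
    """Per-individual fraction of CpGs in each read-depth bin.

    ``bin_edges`` must be strictly increasing; the last bin is open-ended
    if its upper edge is ``inf``.  Fractions per individual sum to 1; on an
    empty set all fractions are 0 and ``attrs['empty']`` is set.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    rows = []
    for j in range(mset.n_individuals):
        counts, _ = np.histogram(mset.total[:, j], bins=edges)
        frac = counts / mset.n_sites if mset.n_sites else np.zeros(len(counts))
        rows.append(frac)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    out = pd.DataFrame(rows, index=mset.individuals, columns=labels)
    out.attrs["empty"] = mset.n_sites == 0
    return out


def window_methylation(
    mset: MethylomeSet,
    window_bp: int,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowSummary]:
    """Coverage-weighted methylation in fixed windows tiled from position 0.

    Per window and individual: sum of methylated reads over sum of total
    reads across the CpGs falling in the window; NaN where that individual
    has zero coverage.  Windows with no CpG at all are reported with
    ``n_informative_cpgs == 0`` and all-NaN methylation (missing, never 0).
    When ``chrom_lengths`` is given the tiling spans each chromosome fully
    (last window truncated); otherwise it runs to the last observed CpG.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    out: list[WindowSummary] = []
    df_idx = pd.DataFrame({"chrom": mset.chrom, "win": mset.pos // window_bp})
    grouped = df_idx.groupby(["chrom", "win"], sort=True).indices
    chroms: dict[str, int] = {}
    for c in mset.chrom:
        chroms.setdefault(str(c), 0)
    for (chrom, win), idx in grouped.items():
        end = (int(win) + 1) * window_bp
        chroms[str(chrom)] = max(chroms[str(chrom)], end)
    if chrom_lengths:
        for c, length in chrom_lengths.items():
            chroms[c] = length
    nan = np.full(mset.n_individuals, np.nan)
    for chrom in sorted(chroms):
        length = chroms[chrom]
        for win in range(int(np.ceil(length / window_bp))):
            start = win * window_bp
            end = min(start + window_bp, length)
            idx = grouped.get((chrom, win))
            if idx is None:
                out.append(WindowSummary(chrom, start, end, nan.copy(), 0))
                continue
            meth_sum = mset.meth[idx].sum(axis=0).astype(float)
            tot_sum = mset.total[idx].sum(axis=0).astype(float)
            frac = np.where(tot_sum > 0, meth_sum / np.maximum(tot_sum, 1), np.nan)
            out.append(WindowSummary(chrom, start, end, frac, len(idx)))
    return out


def write_methylome_tsv(mset: MethylomeSet, path) -> None:
    """Write the merged count matrix as TSV (chrom, pos0, per-individual pairs)."""
    with _open_maybe_gzip(path, "wt") as fh:
        mset.to_frame().to_csv(fh, sep="\t", index=False)


def read_methylome_tsv(path) -> MethylomeSet:
    """Read a matrix written by :func:`write_methylome_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    individuals = [c[:-5] for c in df.columns if c.endswith(".meth")]
    meth = np.column_stack([df[f"{i}.meth"].to_numpy(np.int64) for i in individuals])
    total = np.column_stack([df[f"{i}.total"].to_numpy(np.int64) for i in individuals])
    return MethylomeSet(
        individuals=individuals,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(np.int64),
        meth=meth,
        total=total,
    )
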