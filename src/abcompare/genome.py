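"""Genomic coordinate system, contact-map I/O and covariate tracks.

Everything downstream is indexed against fixed-width bins read from a BED
file (the HiC-Pro "abs bins" convention). Contact maps arrive as sparse
upper-triangle triplets ``binA binB count`` or as dense whitespace matrices;
compartment-score tracks travel as bedGraph. Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import FormatError

__all__ = [
    "GenomeBins",
    "BinSet",
    "ContactMap",
    "CovariateTrack",
    "read_bins",
    "read_contact_map",
    "read_contact_maps",
    "read_dense_matrix",
    "write_contact_map",
    "gc_track",
    "gene_density_track",
    "read_genes",
    "write_scores_bedgraph",
    "read_bedgraph",
]

_CHROM_START_ID = re.compile(r"^(?P<chrom>.+)_(?P<start>\d+)$")


@dataclass(frozen=True)
class GenomeBins:
    """Ordered fixed-width bins of one chromosome.

    Bins are sorted, contiguous and non-overlapping; all have width
    ``resolution`` except possibly the terminal bin. Indices are dense
    ``0..n_bins-1``.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    resolution: int

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def coords(self, index: int) -> tuple[str, int, int]:
        return self.chrom, int(self.starts[index]), int(self.ends[index])

    def index_of(self, start: int) -> int:
        """Bin index containing the coordinate ``start``."""
        i = int(start) // self.resolution
        if not (0 <= i < self.n_bins and self.starts[i] <= start < self.ends[i]):
            raise FormatError(f"coordinate {start} outside bins of {self.chrom}")
        return i

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.starts, "end": self.ends}
        )


class BinSet(Mapping[str, GenomeBins]):
    """All chromosomes of a bins file, with triplet-id resolution.

    Bin ids in HiC-Pro triplet files are resolved via the bins file's 4th
    column when present, else via genome-wide 1-based order; explicit
    ``chrom_start`` ids are always accepted.
    """

    def __init__(self, per_chrom: dict[str, GenomeBins], ids: Sequence[str] | None):
        self._per_chrom = per_chrom
        rows = []
        self._id_lookup: dict[str, tuple[str, int]] = {}
        k = 0
        for chrom, gb in per_chrom.items():
            for i in range(gb.n_bins):
                rows.append((chrom, int(gb.starts[i]), int(gb.ends[i])))
                bin_id = str(ids[k]) if ids is not None else str(k + 1)
                self._id_lookup[bin_id] = (chrom, i)
                k += 1
        self.frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def __getitem__(self, chrom: str) -> GenomeBins:
        return self._per_chrom[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._per_chrom)

    def __len__(self) -> int:
        return len(self._per_chrom)

    @property
    def resolution(self) -> int:
        return next(iter(self._per_chrom.values())).resolution

    def resolve_id(self, bin_id: str) -> tuple[str, int]:
        """Map a triplet-file bin id to ``(chrom, local index)``."""
        hit = self._id_lookup.get(str(bin_id))
        if hit is not None:
            return hit
        m = _CHROM_START_ID.match(str(bin_id))
        if m and m.group("chrom") in self._per_chrom:
            return m.group("chrom"), self[m.group("chrom")].index_of(int(m.group("start")))
        raise FormatError(f"bin id {bin_id!r} not present in bins file")


@dataclass
class ContactMap:
    """Symmetric cis contact-count matrix of one chromosome.

    ``counts`` is dense ``n x n`` with ``counts[i, j] == counts[j, i] >= 0``.
    """

    chrom: str
    counts: np.ndarray
    sample: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise FormatError(f"{self.chrom}: contact matrix must be square")
        if not np.allclose(c, c.T):
            raise FormatError(f"{self.chrom}: contact matrix must be symmetric")
        if np.any(c < 0):
            raise FormatError(f"{self.chrom}: negative contact counts")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class CovariateTrack:
    """Per-bin covariate (GC fraction or gene count); ``mask`` flags bins
    where the covariate is undefined (e.g. all-N sequence)."""

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise FormatError("covariate mask length mismatch")


def _data_lines(path: Path) -> Iterator[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield line.split()


def read_bins(bed_path: str | Path) -> BinSet:
    """Read a BED3/BED4 bins file into per-chromosome :class:`GenomeBins`.

    Enforces sorted, contiguous, non-overlapping bins of one common
    resolution (the terminal bin of each chromosome may be shorter).
    """
    rows = list(_data_lines(Path(bed_path)))
    if not rows:
        raise FormatError(f"{bed_path}: empty bins file")
    has_ids = all(len(r) >= 4 for r in rows)
    chroms: dict[str, list[tuple[int, int]]] = {}
    ids: list[str] = []
    for r in rows:
        if len(r) < 3:
            raise FormatError(f"{bed_path}: need >=3 BED columns, got {r!r}")
        chroms.setdefault(r[0], []).append((int(r[1]), int(r[2])))
        if has_ids:
            ids.append(r[3])

    widths: set[int] = set()
    per_chrom: dict[str, GenomeBins] = {}
    for chrom, iv in chroms.items():
        starts = np.array([s for s, _ in iv], dtype=np.int64)
        ends = np.array([e for _, e in iv], dtype=np.int64)
        if np.any(ends <= starts):
            raise FormatError(f"{chrom}: empty or inverted interval")
        if np.any(np.diff(starts) <= 0):
            raise FormatError(f"{chrom}: bins are unsorted or overlapping")
        if len(starts) > 1 and np.any(starts[1:] != ends[:-1]):
            raise FormatError(f"{chrom}: bins are not contiguous (gap or overlap)")
        w = ends - starts
        body = w[:-1] if len(w) > 1 else w
        if len(set(body.tolist())) > 1:
            raise FormatError(f"{chrom}: mixed bin widths")
        res = int(body[0])
        if len(w) > 1 and w[-1] > res:
            raise FormatError(f"{chrom}: terminal bin wider than resolution")
        widths.add(res)
        per_chrom[chrom] = GenomeBins(chrom, starts, ends, res)
    if len(widths) > 1:
        raise FormatError(f"{bed_path}: mixed resolutions across chromosomes {sorted(widths)}")
    return BinSet(per_chrom, ids if has_ids else None)


def _accumulate(triplets: Iterator[list[str]], binset: BinSet, source: str):
    """Sum triplets into per-chromosome dense upper triangles."""
    upper: dict[str, np.ndarray] = {}
    n_trans = 0
    for r in triplets:
        if len(r) < 3:
            raise FormatError(f"{source}: expected 'binA binB count', got {r!r}")
        value = float(r[2])
        if value < 0:
            raise FormatError(f"{source}: negative count {value}")
        chrom_a, i = binset.resolve_id(r[0])
        chrom_b, j = binset.resolve_id(r[1])
        if chrom_a != chrom_b:
            n_trans += 1
            continue
        if chrom_a not in upper:
            n = binset[chrom_a].n_bins
            upper[chrom_a] = np.zeros((n, n))
        if i > j:
            i, j = j, i
        upper[chrom_a][i, j] += value
    if n_trans:
        warnings.warn(f"{source}: skipped {n_trans} trans (inter-chromosomal) entries")
    return upper


def read_contact_maps(
    triplet_path: str | Path,
    binset: BinSet,
    sample: str = "",
    replicate: str = "",
) -> dict[str, ContactMap]:
    """Read a HiC-Pro-style sparse triplet file into cis contact maps.

    Entries given once (either triangle) are mirrored; duplicate entries for
    the same unordered pair are summed. Chromosomes absent from the file get
    all-zero maps.
    """
    upper = _accumulate(_data_lines(Path(triplet_path)), binset, str(triplet_path))
    out = {}
    for chrom in binset:
        n = binset[chrom].n_bins
        u = upper.get(chrom, np.zeros((n, n)))
        counts = u + u.T - np.diag(np.diag(u))
        out[chrom] = ContactMap(chrom, counts, sample=sample, replicate=replicate)
    return out


def read_contact_map(triplet_path: str | Path, bins: GenomeBins, **labels: str) -> ContactMap:
    """Single-chromosome convenience wrapper around :func:`read_contact_maps`."""
    binset = BinSet({bins.chrom: bins}, None)
    return read_contact_maps(triplet_path, binset, **labels)[bins.chrom]


def read_dense_matrix(path: str | Path, bins: GenomeBins, **labels: str) -> ContactMap:
    """Read a dense whitespace-separated symmetric matrix."""
    counts = np.loadtxt(path)
    if counts.shape != (bins.n_bins, bins.n_bins):
        raise FormatError(f"{path}: matrix shape {counts.shape} does not match {bins.n_bins} bins")
    return ContactMap(bins.chrom, counts, **labels)


def write_contact_map(cmap: ContactMap, binset: BinSet, path: str | Path) -> None:
    """Write upper-triangle triplets using genome-wide 1-based bin ids."""
    offset = 0
    for chrom in binset:
        if chrom == cmap.chrom:
            break
        offset += binset[chrom].n_bins
    iu, ju = np.triu_indices(cmap.n_bins)
    vals = cmap.counts[iu, ju]
    keep = vals != 0
    with open(path, "w") as fh:
        for i, j, v in zip(iu[keep] + offset + 1, ju[keep] + offset + 1, vals[keep]):
            fh.write(f"{i}\t{j}\t{v:g}\n")


def gc_track(fasta_path: str | Path, bins: GenomeBins) -> CovariateTrack:
    """Per-bin GC fraction (G+C)/(A+C+G+T); all-N bins are masked."""
    fa = Fasta(str(fasta_path), rebuild=False)
    if bins.chrom not in fa:
        raise FormatError(f"chromosome {bins.chrom} missing from {fasta_path}")
    seq = str(fa[bins.chrom][:]).upper()
    values = np.full(bins.n_bins, np.nan)
    for i in range(bins.n_bins):
        s = seq[bins.starts[i] : bins.ends[i]]
        gc = s.count("G") + s.count("C")
        at = s.count("A") + s.count("T")
        if gc + at > 0:
            values[i] = gc / (gc + at)
    return CovariateTrack(values)


_GTF_NAME = re.compile(r'gene_(?:name|id)\s+"?([^";]+)"?')


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read gene bodies from BED or GTF/GFF into (chrom, start, end, name).

    GTF/GFF coordinates (1-based, inclusive) are converted to BED
    convention; only ``gene`` feature rows are used.
    """
    p = Path(path)
    rows = []
    if p.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        with open(p) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                m = _GTF_NAME.search(f[8])
                rows.append((f[0], int(f[3]) - 1, int(f[4]), m.group(1) if m else "."))
    else:
        for f in _data_lines(p):
            if len(f) < 3:
                raise FormatError(f"{path}: need >=3 BED columns")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def gene_density_track(annotation_path: str | Path, bins: GenomeBins) -> CovariateTrack:
    """Per-bin count of gene bodies overlapping the bin by >= 1 bp.

    A gene spanning k bins contributes to all k.
    """
    genes = read_genes(annotation_path)
    counts = np.zeros(bins.n_bins)
    chrom_end = int(bins.ends[-1])
    for _, g in genes[genes.chrom == bins.chrom].iterrows():
        if g.end <= 0 or g.start >= chrom_end:
            continue
        first = max(int(g.start), 0) // bins.resolution
        last = (min(int(g.end), chrom_end) - 1) // bins.resolution
        counts[first : min(last, bins.n_bins - 1) + 1] += 1
    return CovariateTrack(counts, mask=np.zeros(bins.n_bins, dtype=bool))


def write_scores_bedgraph(
    bins: GenomeBins,
    values: np.ndarray,
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write a per-bin score track as 4-column bedGraph.

    Masked bins (NaN values) are omitted.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != bins.n_bins:
        raise FormatError(
            f"{bins.chrom}: {values.shape[0]} values for {bins.n_bins} bins"
        )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i in range(bins.n_bins):
            if np.isfinite(values[i]):
                fh.write(
                    f"{bins.chrom}\t{bins.starts[i]}\t{bins.ends[i]}\t{values[i]:.6f}\n"
                )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into (chrom, start, end, value)."""
    rows = []
    for f in _data_lines(Path(path)):
        if len(f) < 4:
            raise FormatError(f"{path}: bedGraph needs 4 columns")
        rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
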