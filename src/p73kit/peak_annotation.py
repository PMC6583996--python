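"""Peak-to-TSS binding annotation across multiple cell types.

A gene is called "bound" by a transcription factor when an overlapping
ChIP-seq peak — a set of peaks from at least ``min_cell_types`` distinct
cell types with a non-empty common intersection, every one of them
motif-positive when ``require_motif`` is set — lies within ``window`` bp of
the gene's transcription start site.  "Within the window" means the common
intersection interval intersects [TSS - window, TSS + window]; both strands
are treated identically.  Defaults encode the 2-of-3 basal-cell-model rule
with a 50 kb window.

Coordinates are BED-style 0-based half-open throughout.  Peaks that merely
abut ([100,200) vs [200,300)) do not overlap.

Motif evidence is an input flag per peak, produced by whatever external
motif scanner the user trusts; a small IUPAC degenerate-consensus matcher is
provided as optional plumbing for users who have peak sequences in hand.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, UsageError, ValidationError

__all__ = [
    "Peak",
    "PeakSet",
    "TSSTable",
    "BindingCall",
    "read_bed",
    "write_bed",
    "read_tss_table",
    "write_tss_table",
    "tss_distance",
    "overlap_groups",
    "annotate_binding",
    "binding_frame",
    "iupac_motif_present",
]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    motif_present: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"peak [{self.start},{self.end}) is empty")


@dataclass
class PeakSet:
    """All peaks called in one cell type (overlaps within the set kept as-is)."""

    cell_type: str
    peaks: list[Peak] = field(default_factory=list)


@dataclass
class TSSTable:
    """Unique gene_id -> (chrom, 0-based TSS position, strand)."""

    rows: pd.DataFrame  # index gene_id; columns chrom, tss, strand

    def __post_init__(self) -> None:
        if self.rows.index.duplicated().any():
            dupes = self.rows.index[self.rows.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene_ids in TSS table: {list(dupes[:5])}")


@dataclass
class BindingCall:
    gene_id: str
    bound: bool
    supporting_cell_types: list[str]
    best_distance: int | None  # bp from TSS to nearest qualifying overlap; 0 if containing


def read_bed(path: str | Path, cell_type: str | None = None,
             motif_column: int | None = None) -> PeakSet:
    """Read a BED3+ file as one cell type's peak set.

    ``motif_column`` is the 1-based column holding a 0/1 (or true/false)
    motif flag.  Without it every peak is treated as motif-positive, with a
    warning, so motif-less workflows degenerate to the pure distance rule.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            if motif_column is not None:
                if len(fields) < motif_column:
                    raise FormatError(
                        f"{path}:{lineno}: motif column {motif_column} absent "
                        f"(row has {len(fields)} columns)"
                    )
                token = fields[motif_column - 1].lower()
                if token in {"1", "true", "t", "yes"}:
                    motif = True
                elif token in {"0", "false", "f", "no"}:
                    motif = False
                else:
                    raise FormatError(f"{path}:{lineno}: bad motif flag {token!r}")
            else:
                motif = True
            peaks.append(Peak(fields[0], start, end, motif))
    if motif_column is None:
        warnings.warn(f"{path}: no motif column given; all peaks assumed motif-positive")
    return PeakSet(cell_type=cell_type or path.stem, peaks=peaks)


def write_bed(ps: PeakSet, path: str | Path, with_motif: bool = True) -> None:
    """Write a peak set as BED (motif flag in column 7 when ``with_motif``)."""
    with open(path, "w") as fh:
        for p in ps.peaks:
            if with_motif:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t0\t.\t{int(p.motif_present)}\n")
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def write_tss_table(tss: TSSTable, path: str | Path) -> None:
    """Write a 0-based TSS table (inverse of :func:`read_tss_table`)."""
    tss.rows.reset_index().to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path, one_based: bool = False) -> TSSTable:
    """Read a TSS TSV (gene_id, chrom, tss, strand); 1-based input converted."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "chrom", "tss", "strand") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.set_index("gene_id")
    df["tss"] = df["tss"].astype(int) - (1 if one_based else 0)
    return TSSTable(rows=df[["chrom", "tss", "strand"]])


def overlap_groups(sets: list[PeakSet]) -> list[dict]:
    """Maximal intervals covered by peaks from >= 2 distinct cell types.

    Returns one record per group: chrom, start, end, the contributing cell
    types (those with a peak intersecting the interval), the member peaks,
    and ``all_motif`` (every member motif-positive).
    """
    if len(sets) < 2:
        raise UsageError("overlap_groups needs at least 2 peak sets")
    names = [s.cell_type for s in sets]
    if len(set(names)) != len(names):
        raise UsageError(f"duplicate cell type names: {names}")
    by_chrom: dict[str, list[tuple[Peak, str]]] = {}
    for s in sets:
        for p in s.peaks:
            by_chrom.setdefault(p.chrom, []).append((p, s.cell_type))
    groups: list[dict] = []
    for chrom, items in sorted(by_chrom.items()):
        # sweep: per-position count of distinct covering cell types
        events: list[tuple[int, int, str]] = []
        for p, ct in items:
            events.append((p.start, 1, ct))
            events.append((p.end, -1, ct))
        events.sort(key=lambda e: (e[0], e[1]))
        depth: dict[str, int] = {}
        open_start: int | None = None
        intervals: list[tuple[int, int]] = []
        for pos, delta, ct in events:
            before = sum(1 for v in depth.values() if v > 0)
            depth[ct] = depth.get(ct, 0) + delta
            after = sum(1 for v in depth.values() if v > 0)
            if before < 2 <= after:
                open_start = pos
            elif before >= 2 > after and open_start is not None:
                if pos > open_start:
                    intervals.append((open_start, pos))
                open_start = None
        # merge abutting intervals produced by event ties
        merged: list[list[int]] = []
        for a, b in intervals:
            if merged and merged[-1][1] >= a:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            members = [(p, ct) for p, ct in items if p.start < b and p.end > a]
            groups.append(
                {
                    "chrom": chrom,
                    "start": a,
                    "end": b,
                    "cell_types": sorted({ct for _, ct in members}),
                    "peaks": [p for p, _ in members],
                    "all_motif": all(p.motif_present for p, _ in members),
                }
            )
    return groups


def _qualifying_intersections(
    sets: list[PeakSet], min_cell_types: int, require_motif: bool
) -> dict[str, list[tuple[int, int, frozenset[str]]]]:
    """Common intersections of one peak from each of >= min_cell_types cell types.

    For each combination of exactly ``min_cell_types`` distinct cell types,
    every non-empty common intersection of one (motif-positive, if required)
    peak per cell type is recorded as (start, end, cell_types), keyed by
    chrom.  Larger supporting sets are captured implicitly: any k+1-type
    overlap contains a k-type one for each sub-combination.
    """
    out: dict[str, list[tuple[int, int, frozenset[str]]]] = {}
    for combo in itertools.combinations(sets, min_cell_types):
        # start from the first set's usable peaks; iteratively intersect
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        first = combo[0]
        for p in first.peaks:
            if require_motif and not p.motif_present:
                continue
            per_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        for s in combo[1:]:
            nxt: dict[str, list[tuple[int, int]]] = {}
            speaks: dict[str, list[Peak]] = {}
            for p in s.peaks:
                if require_motif and not p.motif_present:
                    continue
                speaks.setdefault(p.chrom, []).append(p)
            for chrom, ivals in per_chrom.items():
                for a, b in ivals:
                    for p in speaks.get(chrom, ()):  # noqa: B905
                        lo, hi = max(a, p.start), min(b, p.end)
                        if lo < hi:
                            nxt.setdefault(chrom, []).append((lo, hi))
            per_chrom = nxt
        ctypes = frozenset(s.cell_type for s in combo)
        for chrom, ivals in per_chrom.items():
            out.setdefault(chrom, []).extend((a, b, ctypes) for a, b in ivals)
    return out


def tss_distance(a: int, b: int, pos: int) -> int:
    """bp distance from a TSS at ``pos`` to the half-open interval [a, b).

    0 when the TSS falls inside; ``a - pos`` upstream of the interval and
    ``pos - b`` downstream of it (the gap measured to the interval boundary
    coordinates).
    """
    if pos < a:
        return a - pos
    if pos >= b:
        return pos - b
    return 0


def annotate_binding(
    tss: TSSTable,
    sets: list[PeakSet],
    window: int = 50_000,
    min_cell_types: int = 2,
    require_motif: bool = True,
) -> list[BindingCall]:
    """Call each gene bound/unbound under the k-of-n proximity rule.

    A gene is bound iff some set of peaks from >= ``min_cell_types`` distinct
    cell types has a non-empty common intersection (every peak in the set
    motif-positive when ``require_motif``) at distance <= ``window`` from the
    TSS (:func:`tss_distance`; 0 when the TSS lies inside the intersection).
    ``best_distance`` is the minimal distance over qualifying intersections;
    unbound genes carry no distance.
    """
    if window <= 0:
        raise UsageError("window must be positive")
    if min_cell_types > len(sets):
        raise UsageError(
            f"min_cell_types={min_cell_types} exceeds number of peak sets {len(sets)}"
        )
    inter = _qualifying_intersections(sets, min_cell_types, require_motif)
    calls: list[BindingCall] = []
    for gene_id, row in tss.rows.iterrows():
        pos = int(row["tss"])
        best: int | None = None
        supporters: set[str] = set()
        for a, b, ctypes in inter.get(row["chrom"], ()):  # per-chrom partitioning
            d = tss_distance(a, b, pos)
            if d <= window:
                supporters.update(ctypes)
                if best is None or d < best:
                    best = d
        calls.append(
            BindingCall(
                gene_id=str(gene_id),
                bound=bool(supporters),
                supporting_cell_types=sorted(supporters),
                best_distance=best,
            )
        )
    return calls


def binding_frame(calls: list[BindingCall]) -> pd.DataFrame:
    """BindingCall rows as a frame for TSV output."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "bound": [c.bound for c in calls],
            "supporting_cell_types": [",".join(c.supporting_cell_types) for c in calls],
            "best_distance": [c.best_distance for c in calls],
        }
    )


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def iupac_motif_present(sequence: str, consensus: str, both_strands: bool = True) -> bool:
    """Does an IUPAC degenerate consensus match anywhere in ``sequence``?

    Plumbing for users who want to flag peaks from sequence themselves; no
    motif model ships with the package.
    """
    seq = sequence.upper()
    pats = [consensus.upper()]
    if both_strands:
        pats.append(consensus.upper().translate(_COMPLEMENT)[::-1])
    for pat in pats:
        allowed = [_IUPAC.get(c) for c in pat]
        if any(a is None for a in allowed):
            raise UsageError(f"bad IUPAC consensus {consensus!r}")
        k = len(pat)
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in allowed[j] for j in range(k)):
                return True
    return False
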