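"""Per-sample isoform usage from exon-exon junction read counts.

N-terminal promoter usage is the share of reads supporting the TA first-exon
junction versus the dN first-exon junction:

    ta_pct = 100 * TA / (TA + dN),   dn_pct = 100 * dN / (TA + dN).

C-terminal splice-class usage partitions the reads of the four junctions
leaving E10 (E10-E11, E10-E12, E10-E13, E10-E14).  The E10-E11 class covers
both alpha and beta transcripts and is split proportionally by the resolver
junctions E12-E13 (alpha) and E12-E14 (beta):

    alpha = share(E10-E11) * E12E13 / (E12E13 + E12E14)
    beta  = share(E10-E11) * E12E14 / (E12E13 + E12E14)

so the five reported classes (alpha, beta, gamma_eps, zeta, delta) sum to
100 whenever defined.  Zero denominators yield undefined statistics with an
explicit flag rather than zeros, and samples where a statistic is undefined
are excluded from cross-sample means (n_defined is reported alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, UsageError
from .gene_model import DiagnosticMap, JunctionKey

__all__ = [
    "JunctionCounts",
    "IsoformUsage",
    "CTERM_STATS",
    "USAGE_STATS",
    "read_junction_file",
    "write_junction_file",
    "nterm_usage",
    "cterm_usage",
    "usage_per_sample",
    "aggregate_usage",
    "usage_table",
]

#: C-terminal statistics reported per sample, in output order.
CTERM_STATS = ("alpha", "beta", "gamma_eps", "zeta", "delta")
#: All per-sample percentage statistics.
USAGE_STATS = ("ta_pct", "dn_pct") + CTERM_STATS

_SJTAB_STRAND = {"0": ".", "1": "+", "2": "-"}


@dataclass
class JunctionCounts:
    """Uniquely-mapped junction read counts for one sample."""

    sample_id: str
    counts: dict[JunctionKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0:
                raise UsageError(f"{self.sample_id}: negative count for {key}")

    def get(self, key: JunctionKey) -> int:
        """Count for a junction; an absent key means zero coverage."""
        return self.counts.get(key, 0)


@dataclass
class IsoformUsage:
    """Per-sample N- and C-terminal usage percentages with coverage flags."""

    sample_id: str
    ta_pct: float | None
    dn_pct: float | None
    cterm_pct: dict[str, float]  # keys from CTERM_STATS and/or alpha_beta_unresolved
    nterm_total: int
    cterm_total: int
    resolver_total: int
    nterm_undefined: bool
    cterm_undefined: bool
    ab_unresolved: bool


def read_junction_file(path: str | Path, dialect: str = "sjtab") -> JunctionCounts:
    """Read one sample's junction counts.

    ``sjtab`` is the 9-column spliced-aligner junction tab (chrom,
    intron_start, intron_end, strand code 0/1/2, motif, annotated, unique
    reads, multimapped reads, max overhang); only the unique-read column is
    used.  ``simple`` is a 5-column TSV: chrom, intron_start, intron_end,
    strand, count.  The sample id is the file stem.
    """
    path = Path(path)
    if dialect not in {"sjtab", "simple"}:
        raise UsageError(f"unknown junction dialect {dialect!r}")
    counts: dict[JunctionKey, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            try:
                if dialect == "sjtab":
                    if len(fields) != 9:
                        raise ValueError(f"expected 9 columns, got {len(fields)}")
                    chrom, s, e, strand_code = fields[0], fields[1], fields[2], fields[3]
                    strand = _SJTAB_STRAND.get(strand_code)
                    if strand is None:
                        raise ValueError(f"bad strand code {strand_code!r}")
                    count = int(fields[6])
                else:
                    if len(fields) != 5:
                        raise ValueError(f"expected 5 columns, got {len(fields)}")
                    chrom, s, e, strand = fields[0], fields[1], fields[2], fields[3]
                    if strand not in {"+", "-", "."}:
                        raise ValueError(f"bad strand {strand!r}")
                    count = int(fields[4])
                intron_start, intron_end = int(s), int(e)
                if count < 0:
                    raise ValueError(f"negative count {count}")
                if intron_start > intron_end:
                    raise ValueError("intron_start > intron_end")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            key = JunctionKey(chrom, intron_start, intron_end, strand)
            counts[key] = counts.get(key, 0) + count
    return JunctionCounts(sample_id=path.stem, counts=counts)


def write_junction_file(jc: JunctionCounts, path: str | Path, dialect: str = "sjtab") -> None:
    """Write counts in either junction dialect (inverse of :func:`read_junction_file`)."""
    if dialect not in {"sjtab", "simple"}:
        raise UsageError(f"unknown junction dialect {dialect!r}")
    strand_code = {".": "0", "+": "1", "-": "2"}
    with open(path, "w") as fh:
        for key in sorted(jc.counts):
            n = jc.counts[key]
            if dialect == "sjtab":
                # motif/annotated/multimapped/overhang are placeholders
                fh.write(
                    f"{key.chrom}\t{key.intron_start}\t{key.intron_end}\t"
                    f"{strand_code[key.strand]}\t0\t0\t{n}\t0\t0\n"
                )
            else:
                fh.write(
                    f"{key.chrom}\t{key.intron_start}\t{key.intron_end}\t{key.strand}\t{n}\n"
                )


def _counts_for(jc: JunctionCounts, keys: Mapping[str, JunctionKey],
                strand_blind: bool = True) -> dict[str, int]:
    # sjtab files may record strand as "." (undefined); match on coordinates
    # first and fall back to the exact key.
    by_coord: dict[tuple[str, int, int], int] = {}
    if strand_blind:
        for key, n in jc.counts.items():
            coord = (key.chrom, key.intron_start, key.intron_end)
            by_coord[coord] = by_coord.get(coord, 0) + n
    out = {}
    for name, key in keys.items():
        if strand_blind:
            out[name] = by_coord.get((key.chrom, key.intron_start, key.intron_end), 0)
        else:
            out[name] = jc.get(key)
    return out


def nterm_usage(jc: JunctionCounts, dm: DiagnosticMap) -> tuple[float | None, float | None, int, bool]:
    """N-terminal promoter usage: (ta_pct, dn_pct, total, undefined_flag)."""
    c = _counts_for(jc, dm.nterm)
    total = c["TA"] + c["dN"]
    if total == 0:
        return None, None, 0, True
    return 100.0 * c["TA"] / total, 100.0 * c["dN"] / total, total, False


def cterm_usage(jc: JunctionCounts, dm: DiagnosticMap) -> tuple[dict[str, float], int, int, bool, bool]:
    """C-terminal class percentages.

    Returns (cterm_pct, cterm_total, resolver_total, cterm_undefined,
    ab_unresolved).  ``cterm_pct`` holds alpha/beta/gamma_eps/zeta/delta, or
    ``alpha_beta_unresolved`` in place of alpha and beta when the E10-E11
    class has reads but neither resolver junction does.
    """
    c = _counts_for(jc, dm.cterm)
    r = _counts_for(jc, dm.resolvers)
    total = sum(c.values())
    resolver_total = r["alpha"] + r["beta"]
    if total == 0:
        return {}, 0, resolver_total, True, False
    shares = {name: 100.0 * n / total for name, n in c.items()}
    ab_share = shares.pop("alpha_beta")
    pct = dict(shares)
    if ab_share > 0 and resolver_total == 0:
        pct["alpha_beta_unresolved"] = ab_share
        return pct, total, resolver_total, False, True
    if resolver_total > 0:
        pct["alpha"] = ab_share * r["alpha"] / resolver_total
        pct["beta"] = ab_share * r["beta"] / resolver_total
    else:  # ab_share == 0: nothing to split
        pct["alpha"] = 0.0
        pct["beta"] = 0.0
    return pct, total, resolver_total, False, False


def usage_per_sample(jc: JunctionCounts, dm: DiagnosticMap) -> IsoformUsage:
    """Full per-sample usage record (composition of the two ratio operations)."""
    ta, dn, n_total, n_undef = nterm_usage(jc, dm)
    cterm, c_total, r_total, c_undef, ab_unres = cterm_usage(jc, dm)
    return IsoformUsage(
        sample_id=jc.sample_id,
        ta_pct=ta,
        dn_pct=dn,
        cterm_pct=cterm,
        nterm_total=n_total,
        cterm_total=c_total,
        resolver_total=r_total,
        nterm_undefined=n_undef,
        cterm_undefined=c_undef,
        ab_unresolved=ab_unres,
    )


def _stat_value(u: IsoformUsage, stat: str) -> float | None:
    if stat == "ta_pct":
        return u.ta_pct
    if stat == "dn_pct":
        return u.dn_pct
    return u.cterm_pct.get(stat)


def aggregate_usage(usages: Sequence[IsoformUsage]) -> pd.DataFrame:
    """Unweighted mean of each percentage over samples where it is defined.

    Returns a frame indexed by statistic with columns ``mean_pct`` (NaN when
    no sample defines the statistic) and ``n_defined``.
    """
    if not usages:
        raise UsageError("aggregate_usage: empty usage list")
    stats = list(USAGE_STATS) + ["alpha_beta_unresolved"]
    rows = {}
    for stat in stats:
        values = [v for u in usages if (v := _stat_value(u, stat)) is not None]
        rows[stat] = {
            "mean_pct": sum(values) / len(values) if values else math.nan,
            "n_defined": len(values),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "statistic"
    df["n_defined"] = df["n_defined"].astype(int)
    return df


def usage_table(usages: Iterable[IsoformUsage]) -> pd.DataFrame:
    """Per-sample usage as a flat frame suitable for TSV output."""
    records = []
    for u in usages:
        rec: dict[str, object] = {"sample_id": u.sample_id, "ta_pct": u.ta_pct, "dn_pct": u.dn_pct}
        for stat in CTERM_STATS:
            rec[stat] = u.cterm_pct.get(stat)
        rec["alpha_beta_unresolved"] = u.cterm_pct.get("alpha_beta_unresolved")
        rec.update(
            nterm_total=u.nterm_total,
            cterm_total=u.cterm_total,
            resolver_total=u.resolver_total,
            nterm_undefined=u.nterm_undefined,
            cterm_undefined=u.cterm_undefined,
            ab_unresolved=u.ab_unresolved,
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)
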