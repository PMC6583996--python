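"""Labeled exon models and diagnostic splice junctions.

A p53-family gene such as *TP73* expresses N-terminal variants from
alternative promoters (TA from an upstream first exon, dN from an internal
first exon) and C-terminal variants (alpha, beta, gamma, delta, epsilon,
zeta) by alternative 3' splicing.  Each variant class is identified by a
single diagnostic exon-exon junction: the unique donor/acceptor exon pair
whose spliced reads can only come from transcripts of that class.  This
module parses a labeled exon table and turns a class -> (donor, acceptor)
specification into concrete intronic intervals that junction-count files can
be matched against.

Coordinates: exons are 1-based inclusive genomic positions; a junction is
stored as the 1-based first and last intronic base, in genomic orientation
(``intron_start <= intron_end``) regardless of strand.  This matches the
junction-tab convention of spliced aligners, so real junction files match
exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import FormatError, GeometryError, ValidationError

__all__ = [
    "Exon",
    "ExonModel",
    "JunctionKey",
    "DiagnosticMap",
    "DEFAULT_CLASS_SPEC",
    "NTERM_CLASSES",
    "CTERM_CLASSES",
    "RESOLVER_CLASSES",
    "load_exon_table",
    "write_exon_table",
    "load_class_spec",
    "derive_diagnostic_junctions",
]

EXON_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "label", "start", "end"]

#: Default diagnostic-junction specification for TP73.  TA and dN first exons
#: (E3 and E3') splice to the common acceptor E4; C-terminal classes are
#: distinguished by which exon follows E10, and alpha vs beta by which exon
#: follows E12.  Genomic coordinates of the labeled exons are user input.
DEFAULT_CLASS_SPEC: dict[str, tuple[str, str]] = {
    "TA": ("E3", "E4"),
    "dN": ("E3'", "E4"),
    "alpha_beta": ("E10", "E11"),
    "gamma_eps": ("E10", "E12"),
    "zeta": ("E10", "E13"),
    "delta": ("E10", "E14"),
    "alpha": ("E12", "E13"),
    "beta": ("E12", "E14"),
}

NTERM_CLASSES = ("TA", "dN")
CTERM_CLASSES = ("alpha_beta", "gamma_eps", "zeta", "delta")
RESOLVER_CLASSES = ("alpha", "beta")


@dataclass(frozen=True)
class Exon:
    label: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"exon {self.label!r}: start {self.start} > end {self.end}"
            )


@dataclass
class ExonModel:
    """A gene's labeled exons on one chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        labels = [e.label for e in self.exons]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate exon labels: {sorted(dupes)}")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        self._by_label = {e.label: e for e in self.exons}

    def __getitem__(self, label: str) -> Exon:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(
                f"exon label {label!r} not in model for {self.gene_id} "
                f"(have {sorted(self._by_label)})"
            ) from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label


@dataclass(frozen=True, order=True)
class JunctionKey:
    """An intron interval: 1-based first and last intronic base."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValidationError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )


@dataclass(frozen=True)
class DiagnosticMap:
    """Diagnostic junctions for one gene, grouped by what they diagnose.

    ``nterm`` separates the alternative promoters (TA vs dN), ``cterm`` the
    four junction classes downstream of E10, and ``resolvers`` split the
    E10-E11 class into alpha vs beta via the E12-E13 / E12-E14 junctions.
    """

    nterm: Mapping[str, JunctionKey]
    cterm: Mapping[str, JunctionKey]
    resolvers: Mapping[str, JunctionKey]

    def __post_init__(self) -> None:
        keys = list(self.nterm.values()) + list(self.cterm.values()) + list(
            self.resolvers.values()
        )
        if len(set(keys)) != len(keys):
            raise ValidationError("diagnostic junctions must be distinct")
        chroms = {k.chrom for k in keys}
        strands = {k.strand for k in keys}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                "all diagnostic junctions must share one chrom and strand"
            )

    def all_junctions(self) -> dict[str, JunctionKey]:
        out: dict[str, JunctionKey] = {}
        out.update(self.nterm)
        out.update(self.cterm)
        out.update(self.resolvers)
        return out


def load_exon_table(path: str | Path) -> ExonModel:
    """Read a labeled exon table (TSV: gene_id, chrom, strand, label, start, end)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"label": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty exon table") from None
    missing = [c for c in EXON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: exon table has no rows")
    genes = df["gene_id"].unique()
    if len(genes) != 1:
        raise FormatError(f"{path}: expected one gene_id, found {list(genes)}")
    chroms = df["chrom"].unique()
    strands = df["strand"].unique()
    if len(chroms) != 1 or len(strands) != 1:
        raise FormatError(f"{path}: exon rows span multiple chrom/strand values")
    exons = [
        Exon(label=row.label, start=int(row.start), end=int(row.end))
        for row in df.itertuples()
    ]
    return ExonModel(
        gene_id=str(genes[0]), chrom=str(chroms[0]), strand=str(strands[0]), exons=exons
    )


def write_exon_table(model: ExonModel, path: str | Path) -> None:
    """Inverse of :func:`load_exon_table` (field-for-field round trip)."""
    df = pd.DataFrame(
        {
            "gene_id": model.gene_id,
            "chrom": model.chrom,
            "strand": model.strand,
            "label": [e.label for e in model.exons],
            "start": [e.start for e in model.exons],
            "end": [e.end for e in model.exons],
        },
        columns=EXON_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


_SPEC_LINE = re.compile(r"^\s*([^=#\s][^=]*?)\s*=\s*([^,\s]+)\s*,\s*([^,\s]+)\s*$")


def load_class_spec(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a class-spec file: one ``class = donorLabel,acceptorLabel`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    spec: dict[str, tuple[str, str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _SPEC_LINE.match(line)
        if not m:
            raise FormatError(f"{path}:{lineno}: cannot parse class spec line {raw!r}")
        name, donor, acceptor = m.group(1), m.group(2), m.group(3)
        if name in spec:
            raise FormatError(f"{path}:{lineno}: duplicate class {name!r}")
        spec[name] = (donor, acceptor)
    if not spec:
        raise FormatError(f"{path}: empty class spec")
    return spec


def _junction_for_pair(model: ExonModel, donor_label: str, acceptor_label: str) -> JunctionKey:
    donor = model[donor_label]
    acceptor = model[acceptor_label]
    # Donor must be 5' of acceptor in transcription order; genomically that is
    # left-of for + strand and right-of for - strand.
    left, right = (donor, acceptor) if donor.start <= acceptor.start else (acceptor, donor)
    if model.strand == "+" and left is not donor:
        raise GeometryError(
            f"{donor_label} is genomically downstream of {acceptor_label} on + strand"
        )
    if model.strand == "-" and left is donor:
        raise GeometryError(
            f"{donor_label} is genomically upstream of {acceptor_label} on - strand"
        )
    if left.end + 1 > right.start - 1:
        raise GeometryError(
            f"exons {donor_label} and {acceptor_label} overlap or abut: no intron"
        )
    return JunctionKey(
        chrom=model.chrom,
        intron_start=left.end + 1,
        intron_end=right.start - 1,
        strand=model.strand,
    )


def derive_diagnostic_junctions(
    model: ExonModel,
    class_spec: Mapping[str, tuple[str, str]] = DEFAULT_CLASS_SPEC,
) -> DiagnosticMap:
    """Turn a class -> (donor, acceptor) spec into concrete junction intervals.

    Raises ``KeyError`` if a referenced exon label is absent from the model
    and :class:`GeometryError` if a donor/acceptor pair has no intron between
    them.
    """
    junctions = {
        name: _junction_for_pair(model, donor, acceptor)
        for name, (donor, acceptor) in class_spec.items()
    }
    missing = [
        name
        for group in (NTERM_CLASSES, CTERM_CLASSES, RESOLVER_CLASSES)
        for name in group
        if name not in junctions
    ]
    if missing:
        raise KeyError(f"class spec missing required classes: {missing}")
    return DiagnosticMap(
        nterm={name: junctions[name] for name in NTERM_CLASSES},
        cterm={name: junctions[name] for name in CTERM_CLASSES},
        resolvers={name: junctions[name] for name in RESOLVER_CLASSES},
    )
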