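"""Seeded generators for every input format the analysis stages consume.

Each generator plants a known truth (isoform proportions, per-cluster joint
expression probabilities, a one-factor variance fraction and signature gene
list, a bound-gene set) and returns it in a :class:`SimTruth` record so
recovery tests can compare estimates against ground truth.  A fixed seed
yields identical output; every file written by the CLI round-trips through
the corresponding reader.

Study conditions emulated:

* junction counts: multinomial reads over the diagnostic junctions of a
  TP73-like exon model, sequencing depth Poisson, N- and C-terminal read
  pools independent;
* single-cell counts: clustered negative-binomial baseline with ERCC-like
  spike-in features, marker genes driven by planted joint p73/p63 status,
  and optional cells constructed to violate exactly one QC rule each (plus
  exact-boundary decoy cells that must survive QC);
* reprogramming expression: baseline + one latent factor on a planted
  signature gene subset + Gaussian noise, scaled so the factor owns an
  exact share of total variance;
* peaks and TSS: bound genes receive motif-positive overlapping peaks in
  >=2 cell types within the window; decoys probe each boundary rule
  (single cell type, motif-negative overlap, overlap at window + 1 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .gene_model import (
    DEFAULT_CLASS_SPEC,
    DiagnosticMap,
    Exon,
    ExonModel,
    derive_diagnostic_junctions,
)
from .isoform_usage import JunctionCounts
from .peak_annotation import Peak, PeakSet, TSSTable
from .sc_coexpression import CellMatrix

__all__ = [
    "SimTruth",
    "toy_exon_model",
    "toy_diagnostic_map",
    "isoform_props",
    "SKIN_NTERM_PROPS",
    "SKIN_CTERM_PROPS",
    "ISOFORM_CLASSES",
    "simulate_junction_counts",
    "expected_usage",
    "simulate_cell_matrix",
    "simulate_reprogram_matrix",
    "simulate_peaks_and_tss",
]


@dataclass
class SimTruth:
    """Planted parameters of one simulation scenario."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# toy gene model
# --------------------------------------------------------------------------

def toy_exon_model() -> ExonModel:
    """A synthetic TP73-like exon model (labels real, coordinates invented).

    Carries the eight labeled exons needed by the default diagnostic-class
    spec on an invented + strand locus; real analyses supply their own exon
    table extracted from genome annotation.
    """
    coords = {
        "E3": (1_001, 1_100),
        "E3'": (1_301, 1_400),
        "E4": (1_601, 1_700),
        "E10": (5_001, 5_100),
        "E11": (5_301, 5_400),
        "E12": (5_601, 5_700),
        "E13": (5_901, 6_000),
        "E14": (6_201, 6_300),
    }
    exons = [Exon(label, s, e) for label, (s, e) in coords.items()]
    return ExonModel(gene_id="TP73_synthetic", chrom="chr1", strand="+", exons=exons)


def toy_diagnostic_map() -> DiagnosticMap:
    return derive_diagnostic_junctions(toy_exon_model(), DEFAULT_CLASS_SPEC)


# --------------------------------------------------------------------------
# junction counts
# --------------------------------------------------------------------------

#: Full isoform classes: N-terminal promoter x C-terminal splice class.
ISOFORM_CLASSES = tuple(
    f"{n}_{c}" for n in ("TA", "dN") for c in ("alpha", "beta", "gamma_eps", "zeta", "delta")
)

#: Skin-like N-terminal promoter proportions (dN-dominant).
SKIN_NTERM_PROPS = {"TA": 0.133, "dN": 0.867}

#: Skin-like C-terminal class proportions (alpha/beta-dominant), normalized
#: to sum exactly to 1.
_RAW_CTERM = {"alpha": 0.752, "beta": 0.202, "gamma_eps": 0.030, "zeta": 0.010, "delta": 0.008}
SKIN_CTERM_PROPS = {k: v / sum(_RAW_CTERM.values()) for k, v in _RAW_CTERM.items()}

# junction(s) diagnostic for each C-terminal class
_CTERM_JUNCTION = {"alpha": "alpha_beta", "beta": "alpha_beta",
                   "gamma_eps": "gamma_eps", "zeta": "zeta", "delta": "delta"}


def isoform_props(
    nterm: Mapping[str, float] = SKIN_NTERM_PROPS,
    cterm: Mapping[str, float] = SKIN_CTERM_PROPS,
) -> dict[str, float]:
    """Outer product of independent N- and C-terminal proportions."""
    return {
        f"{n}_{c}": pn * pc for n, pn in nterm.items() for c, pc in cterm.items()
    }


def expected_usage(props: Mapping[str, float]) -> dict[str, float]:
    """Percentages the quantifier should recover, from full-isoform proportions."""
    pn = {n: sum(v for k, v in props.items() if k.startswith(f"{n}_")) for n in ("TA", "dN")}
    pc = {c: sum(v for k, v in props.items() if k.endswith(f"_{c}"))
          for c in ("alpha", "beta", "gamma_eps", "zeta", "delta")}
    out = {"ta_pct": 100 * pn["TA"] / (pn["TA"] + pn["dN"]),
           "dn_pct": 100 * pn["dN"] / (pn["TA"] + pn["dN"])}
    ctotal = sum(pc.values())
    out.update({c: 100 * v / ctotal for c, v in pc.items()})
    return out


def simulate_junction_counts(
    props: Mapping[str, float] | None = None,
    n_samples: int = 100,
    depth: float = 2_000,
    junction_efficiency: Mapping[str, float] | None = None,
    seed: int = 0,
    dm: DiagnosticMap | None = None,
) -> tuple[list[JunctionCounts], SimTruth]:
    """Draw per-sample junction counts from planted isoform proportions.

    ``props`` maps :data:`ISOFORM_CLASSES` to proportions summing to 1
    (default: skin-like dN/alpha-dominant mix).  Per sample the N-terminal
    read pool is Poisson(``depth``) split multinomially between the TA and
    dN junctions, and independently the C-terminal pool is Poisson(``depth``)
    split over the six C-terminal junctions (four E10-x class junctions and
    the two E12-x resolvers).  ``junction_efficiency`` optionally scales
    individual junction capture probabilities (keys: TA, dN, alpha_beta,
    gamma_eps, zeta, delta, alpha, beta; default 1 everywhere).
    """
    props = dict(props) if props is not None else isoform_props()
    if set(props) != set(ISOFORM_CLASSES):
        raise UsageError(f"props must cover exactly {sorted(ISOFORM_CLASSES)}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise UsageError(f"isoform proportions sum to {total}, expected 1")
    if any(v < 0 for v in props.values()):
        raise UsageError("isoform proportions must be non-negative")
    if depth < 0:
        raise UsageError("depth must be >= 0")
    eff = {k: 1.0 for k in ("TA", "dN", "alpha_beta", "gamma_eps", "zeta", "delta", "alpha", "beta")}
    if junction_efficiency:
        eff.update(junction_efficiency)
    dm = dm or toy_diagnostic_map()
    rng = np.random.default_rng(seed)

    pn = {n: sum(v for k, v in props.items() if k.startswith(f"{n}_")) for n in ("TA", "dN")}
    nterm_w = np.array([pn["TA"] * eff["TA"], pn["dN"] * eff["dN"]])
    nterm_p = nterm_w / nterm_w.sum()

    pc = {c: sum(v for k, v in props.items() if k.endswith(f"_{c}"))
          for c in ("alpha", "beta", "gamma_eps", "zeta", "delta")}
    # six C-terminal junctions: E10-E11 carries alpha+beta; resolvers carry
    # alpha and beta individually
    cterm_names = ["alpha_beta", "gamma_eps", "zeta", "delta", "alpha", "beta"]
    cterm_w = np.array([
        (pc["alpha"] + pc["beta"]) * eff["alpha_beta"],
        pc["gamma_eps"] * eff["gamma_eps"],
        pc["zeta"] * eff["zeta"],
        pc["delta"] * eff["delta"],
        pc["alpha"] * eff["alpha"],
        pc["beta"] * eff["beta"],
    ])
    cterm_p = cterm_w / cterm_w.sum()

    nterm_keys = [dm.nterm["TA"], dm.nterm["dN"]]
    cterm_keys = [dm.cterm["alpha_beta"], dm.cterm["gamma_eps"], dm.cterm["zeta"],
                  dm.cterm["delta"], dm.resolvers["alpha"], dm.resolvers["beta"]]

    samples = []
    for i in range(n_samples):
        counts: dict = {}
        n1 = rng.poisson(depth)
        for key, c in zip(nterm_keys, rng.multinomial(n1, nterm_p)):
            if c:
                counts[key] = int(c)
        n2 = rng.poisson(depth)
        for key, c in zip(cterm_keys, rng.multinomial(n2, cterm_p)):
            if c:
                counts[key] = int(c)
        samples.append(JunctionCounts(sample_id=f"sample{i:04d}", counts=counts))
    truth = SimTruth(
        scenario="junction_counts",
        seed=seed,
        params={
            "props": props,
            "expected": expected_usage(props),
            "depth": depth,
            "efficiency": eff,
            "cterm_junction_names": cterm_names,
        },
    )
    return samples, truth


# --------------------------------------------------------------------------
# single-cell counts
# --------------------------------------------------------------------------

STATUSES = ("a-b-", "a+b-", "a-b+", "a+b+")

_FAIL_MODES = ("genes", "counts", "spikein")


def _nb_counts(rng: np.random.Generator, mean: float, theta: float, size) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture (mean, dispersion theta)."""
    lam = rng.gamma(shape=theta, scale=mean / theta, size=size)
    return rng.poisson(lam)


def simulate_cell_matrix(
    n_clusters: int = 2,
    cells_per_cluster: int = 100,
    joint_status_probs: Sequence[Mapping[str, float]] | None = None,
    n_genes: int = 2_000,
    nb_mean: float = 100.0,
    nb_theta: float = 0.5,
    n_spikein: int = 20,
    spikein_fraction: float = 0.05,
    qc_fail_fraction: float = 0.0,
    gene_a: str = "Trp73",
    gene_b: str = "Trp63",
    seed: int = 0,
) -> tuple[CellMatrix, SimTruth]:
    """Simulate a clustered gene x cell count matrix with planted truth.

    Baseline genes are negative binomial; spike-in features contribute
    ``spikein_fraction`` of each healthy cell's reads in expectation.  Two
    marker genes are driven by a per-cell joint status drawn from the
    cluster's ``joint_status_probs`` (keys ``a-b-``, ``a+b-``, ``a-b+``,
    ``a+b+``): positive markers get counts far above the log-normalized 0.5
    threshold, negative markers get zero, so planted status and thresholded
    status coincide.

    When ``qc_fail_fraction`` > 0, that fraction of cells is rebuilt to
    violate exactly one QC rule each (cycling genes -> counts -> spike-in),
    and three extra boundary decoy cells sit exactly at 900 detected genes,
    75,000 total counts and 12.0% spike-in, all of which must be retained.
    QC-constructed cells are marker-negative.
    """
    n_cells = n_clusters * cells_per_cluster
    if n_cells <= 0:
        raise UsageError("need at least one cell")
    if joint_status_probs is None:
        joint_status_probs = [
            {"a-b-": 0.25, "a+b-": 0.25, "a-b+": 0.25, "a+b+": 0.25}
        ] * n_clusters
    if len(joint_status_probs) != n_clusters:
        raise UsageError("joint_status_probs must have one entry per cluster")
    probs = []
    for i, p in enumerate(joint_status_probs):
        vec = np.array([p.get(s, 0.0) for s in STATUSES], dtype=float)
        if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
            raise UsageError(f"cluster {i}: joint status probabilities invalid")
        probs.append(vec)
    if not 0 <= qc_fail_fraction <= 1:
        raise UsageError("qc_fail_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    base_genes = [f"G{i:05d}" for i in range(n_genes)]
    spike_genes = [f"ERCC-{i:05d}" for i in range(n_spikein)]
    genes = base_genes + [gene_a, gene_b] + spike_genes
    spikein = pd.Series(
        [False] * (n_genes + 2) + [True] * n_spikein, index=pd.Index(genes, name="gene_id")
    )
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    clusters = [f"cluster{i % n_clusters}" for i in range(n_cells)]

    X = np.zeros((len(genes), n_cells), dtype=np.int64)
    X[:n_genes] = _nb_counts(rng, nb_mean, nb_theta, (n_genes, n_cells))
    # spike-ins: target fraction f of total reads => spike total = f/(1-f) * base total
    base_totals = X[:n_genes].sum(axis=0)
    spike_target = spikein_fraction / (1 - spikein_fraction) * base_totals
    X[n_genes + 2:] = rng.poisson(spike_target / n_spikein, size=(n_spikein, n_cells))

    # planted joint statuses and marker counts
    status = np.empty(n_cells, dtype=object)
    ia, ib = n_genes, n_genes + 1
    for c in range(n_cells):
        k = rng.choice(4, p=probs[int(c % n_clusters)])
        status[c] = STATUSES[k]
        a_pos = STATUSES[k][1] == "+"
        b_pos = STATUSES[k][3] == "+"
        X[ia, c] = 40 + rng.poisson(20) if a_pos else 0
        X[ib, c] = 40 + rng.poisson(20) if b_pos else 0

    # QC-rule violators and boundary decoys (counts rebuilt deterministically)
    fail_reasons: dict[str, str] = {}
    boundary_cells: list[str] = []
    n_fail = int(round(qc_fail_fraction * n_cells))
    if n_fail or qc_fail_fraction > 0:
        order = rng.permutation(n_cells)
        chosen = list(order[: n_fail + 3])
        for j, c in enumerate(chosen):
            col = np.zeros(len(genes), dtype=np.int64)
            if j < n_fail:
                mode = _FAIL_MODES[j % 3]
                if mode == "genes":  # 899 genes, total >= 75k, spike < 12%
                    col[:899] = 100
                    col[n_genes + 2:] = 5_000 // n_spikein
                elif mode == "counts":  # total < 75k, genes >= 900, spike < 12%
                    col[:1_500] = 40
                    col[n_genes + 2:] = 3_000 // n_spikein
                else:  # spike > 12%, others fine
                    col[:1_500] = 60
                    col[n_genes + 2:] = 30_000 // n_spikein
                fail_reasons[cells[c]] = mode
            else:
                mode = _FAIL_MODES[j - n_fail]
                if mode == "genes":  # exactly 900 detected genes
                    col[:900] = 100
                    col[n_genes + 2:] = 5_000 // n_spikein
                elif mode == "counts":  # exactly 75,000 total counts
                    col[:1_400] = 50
                    col[n_genes + 2:] = 5_000 // n_spikein
                else:  # exactly 12.0% spike-in
                    col[:1_100] = 80
                    col[n_genes + 2:] = 12_000 // n_spikein
                boundary_cells.append(cells[c])
            X[:, c] = col
            status[c] = "a-b-"

    counts = pd.DataFrame(X, index=spikein.index, columns=pd.Index(cells, name="cell_id"))
    cell_meta = pd.DataFrame(
        {"cluster": clusters, "stage": "adult"}, index=counts.columns
    )
    matrix = CellMatrix(counts=counts, spikein=spikein, cell_meta=cell_meta, mode="counts")
    truth = SimTruth(
        scenario="cell_matrix",
        seed=seed,
        params={
            "joint_status_probs": {f"cluster{i}": dict(zip(STATUSES, p)) for i, p in enumerate(probs)},
            "status": dict(zip(cells, status)),
            "cluster": dict(zip(cells, clusters)),
            "qc_fail": fail_reasons,
            "boundary_cells": boundary_cells,
            "gene_a": gene_a,
            "gene_b": gene_b,
        },
    )
    return matrix, truth


# --------------------------------------------------------------------------
# reprogramming expression matrix
# --------------------------------------------------------------------------

def simulate_reprogram_matrix(
    n_samples: int = 9,
    n_genes: int = 2_000,
    n_signature: int = 250,
    factor_variance_fraction: float = 0.88,
    noise_sd: float = 0.1,
    baseline: float = 10.0,
    positive_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """One-latent-factor sample x gene matrix with an exact variance split.

    ``n_signature`` genes carry nonzero factor loadings (signs split
    ``positive_fraction`` up / rest down); everything else is baseline plus
    N(0, noise_sd^2) noise.  The variance split is exact in-sample, not just
    in expectation: factor scores are standardized to unit sample variance,
    the noise matrix is centered, orthogonalized against the factor scores
    and rescaled to a total per-gene sample variance of exactly
    n_genes * noise_sd^2, and the loadings are scaled so the factor owns
    ``factor_variance_fraction`` of the total.  With a handful of samples an
    expectation-level split would wander by several points per draw, which
    would say nothing about the estimator; the exact split makes recovery
    error attributable to the estimator alone.
    """
    if not 0 < factor_variance_fraction < 1:
        raise UsageError("factor_variance_fraction must be in (0, 1)")
    if n_signature > n_genes:
        raise UsageError(f"n_signature={n_signature} exceeds n_genes={n_genes}")
    if n_samples < 3:
        raise UsageError("need at least 3 samples")
    rng = np.random.default_rng(seed)

    s = rng.normal(size=n_samples)
    s = (s - s.mean()) / s.std(ddof=1)  # exact unit sample variance

    sig_idx = rng.choice(n_genes, size=n_signature, replace=False)
    w = np.zeros(n_genes)
    mags = rng.uniform(0.5, 1.5, size=n_signature)
    signs = np.where(rng.random(n_signature) < positive_fraction, 1.0, -1.0)
    w[sig_idx] = mags * signs
    # scale loadings: f = W / (W + G * sd^2)  with W = sum of squared loadings
    f = factor_variance_fraction
    if noise_sd > 0:
        target_W = f / (1 - f) * n_genes * noise_sd**2
        w *= np.sqrt(target_W / np.sum(w**2))
        noise = rng.normal(scale=noise_sd, size=(n_samples, n_genes))
        noise -= noise.mean(axis=0)
        noise -= np.outer(s, s @ noise) / (s @ s)  # orthogonal to the factor
        total_noise_var = noise.var(axis=0, ddof=1).sum()
        noise *= np.sqrt(n_genes * noise_sd**2 / total_noise_var)
    else:  # noiseless limit: the factor owns all variance
        noise = np.zeros((n_samples, n_genes))
    values = baseline + np.outer(s, w) + noise
    shift = min(values.min(), 0.0)
    values -= shift  # uniform shift keeps non-negativity without touching the PCA

    gene_ids = [f"GENE{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i}" for i in range(n_samples)]
    m = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                     columns=pd.Index(gene_ids, name="gene_id"))
    signature = [gene_ids[i] for i in sorted(sig_idx)]
    truth = SimTruth(
        scenario="reprogram_matrix",
        seed=seed,
        params={
            "factor_variance_fraction": f,
            "signature_genes": signature,
            "up_genes": [gene_ids[i] for i in sorted(sig_idx) if w[i] > 0],
            "down_genes": [gene_ids[i] for i in sorted(sig_idx) if w[i] < 0],
            "factor_scores": dict(zip(sample_ids, s)),
        },
    )
    return m, truth


# --------------------------------------------------------------------------
# peaks and TSS
# --------------------------------------------------------------------------

_DECOY_KINDS = ("single_cell_type", "motif_negative", "outside_window", "no_peaks")


def simulate_peaks_and_tss(
    n_genes: int = 200,
    bound_fraction: float = 0.3,
    n_cell_types: int = 3,
    window: int = 50_000,
    peak_len: int = 500,
    n_peaks_per_type: int = 500,
    decoys: bool = True,
    seed: int = 0,
) -> tuple[list[PeakSet], TSSTable, SimTruth]:
    """Peak sets per cell type + a TSS table with a planted bound-gene set.

    Bound genes receive motif-positive mutually overlapping peaks in >= 2
    cell types within ``window`` of the TSS.  When ``decoys`` is on, unbound
    genes cycle through boundary probes: a peak in one cell type only, a
    motif-negative overlap, an overlap whose distance from the TSS is
    exactly ``window + 1`` bp, and no peaks at all.  Remaining peak capacity
    is filled with random background peaks in a region far from every TSS
    window, so the planted truth is exact.
    """
    if not 0 <= bound_fraction <= 1:
        raise UsageError("bound_fraction must be in [0, 1]")
    if n_cell_types < 2:
        raise UsageError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    spacing = 2 * window + 20 * peak_len  # windows of adjacent genes cannot share peaks
    origin = 10_000_000  # background region is [0, origin - window)
    cell_types = [f"celltype{i}" for i in range(n_cell_types)]
    peaks: dict[str, list[Peak]] = {ct: [] for ct in cell_types}

    gene_ids, tss_pos, strands = [], [], []
    bound_genes: list[str] = []
    decoy_kind: dict[str, str] = {}
    decoy_cycle = 0
    for g in range(n_genes):
        gene = f"gene{g:04d}"
        tss = origin + g * spacing
        gene_ids.append(gene)
        tss_pos.append(tss)
        strands.append("+" if rng.random() < 0.5 else "-")
        jitter = int(rng.integers(-40, 41))

        def _overlapping(center: int, k: int, motif: bool) -> None:
            chosen = rng.choice(n_cell_types, size=k, replace=False)
            for ct_i in chosen:
                a = center - peak_len // 2 - int(rng.integers(0, 50))
                b = center + peak_len // 2 + int(rng.integers(0, 50))
                peaks[cell_types[ct_i]].append(Peak(chrom, a, b, motif))

        if rng.random() < bound_fraction:
            bound_genes.append(gene)
            offset = int(rng.integers(-(window - peak_len), window - peak_len))
            k = int(rng.integers(2, n_cell_types + 1))
            _overlapping(tss + offset, k, motif=True)
        elif decoys:
            kind = _DECOY_KINDS[decoy_cycle % len(_DECOY_KINDS)]
            decoy_cycle += 1
            decoy_kind[gene] = kind
            if kind == "single_cell_type":
                ct = cell_types[int(rng.integers(n_cell_types))]
                peaks[ct].append(Peak(chrom, tss + jitter, tss + jitter + peak_len, True))
            elif kind == "motif_negative":
                _overlapping(tss + jitter, 2, motif=False)
            elif kind == "outside_window":
                # intersection starts exactly window + 1 bp right of the TSS
                a = tss + window + 1
                peaks[cell_types[0]].append(Peak(chrom, a, a + peak_len, True))
                peaks[cell_types[1]].append(Peak(chrom, a - 100, a + peak_len - 100, True))
            # "no_peaks": nothing

    # background far from every gene window
    bg_hi = origin - window - 10 * peak_len
    for ct in cell_types:
        n_bg = max(0, n_peaks_per_type - len(peaks[ct]))
        starts = rng.integers(0, bg_hi, size=n_bg)
        motifs = rng.random(n_bg) < 0.5
        for a, mo in zip(starts, motifs):
            peaks[ct].append(Peak(chrom, int(a), int(a) + peak_len, bool(mo)))

    peak_sets = [PeakSet(cell_type=ct, peaks=peaks[ct]) for ct in cell_types]
    tss = TSSTable(
        rows=pd.DataFrame(
            {"chrom": chrom, "tss": tss_pos, "strand": strands},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    truth = SimTruth(
        scenario="peaks_and_tss",
        seed=seed,
        params={
            "bound_genes": bound_genes,
            "decoy_kind": decoy_kind,
            "window": window,
            "cell_types": cell_types,
        },
    )
    return peak_sets, tss, truth
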