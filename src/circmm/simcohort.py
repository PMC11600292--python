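"""Synthetic myeloma cohort generator built on a kinetic circRNA-dilution model.

The model: each RNA species is synthesized at a constant rate k_syn and lost
by first-order decay (k_deg) plus dilution through cell division at the
exponential growth rate mu, so its per-cell steady state is
C* = k_syn / (k_deg + mu). Because circRNAs decay much more slowly than their
linear hosts, they accumulate in slowly proliferating cells and are diluted
in fast proliferating ones — the mechanism the downstream analysis probes.

A whole bone-marrow sample is a (p, 1-p) mixture of a plasma-cell compartment
and an "other marrow" compartment; a purified plasma-cell sample uses the
plasma compartment only. A latent per-patient severity s couples disease
aggressiveness to the observables: log-linearly increasing plasma-cell growth,
decreasing non-plasma growth (marrow suppression), increasing plasma-cell
fraction (logit-linear inside 10%-90%) and a proportional-hazards effect on
overall survival. Counts are negative binomial (variance = mean + phi*mean^2);
per-caller BSJ detection is thinned by caller sensitivity; survival is
exponential with administrative censoring.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .circconsensus import CALLER_A, CALLER_B, AnnotationDB, BsjCall, CircId
from .containers import ExpressionMatrix, SampleRecord, samples_to_frame
from .normquant import circ_linear_ratio
from .prolifscore import load_signatures

DB_NAMES = ("circatlas", "circpedia", "circbase")
IG_GENES = ("IGHG1", "IGHG3", "IGHA1", "IGHM", "IGKC", "IGLC1", "IGLC2", "JCHAIN")


class DegenerateSteadyStateError(ValueError):
    """k_deg + mu = 0: the species has no finite steady state."""


@dataclass(frozen=True)
class KineticParams:
    """Synthesis (molecules/h) and first-order decay (1/h) rates per species."""

    k_syn_circ: float
    k_syn_lin: float
    k_deg_circ: float
    k_deg_lin: float

    def __post_init__(self) -> None:
        for name in ("k_syn_circ", "k_syn_lin", "k_deg_circ", "k_deg_lin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def steady_state_abundance(k: KineticParams, mu: float) -> tuple[float, float]:
    """Per-cell steady-state molecule counts (circular, linear) at growth rate mu.

    Strictly decreasing in mu for fixed kinetics.
    """
    if mu < 0:
        raise ValueError("growth rate must be non-negative")
    if k.k_deg_circ + mu <= 0 or k.k_deg_lin + mu <= 0:
        raise DegenerateSteadyStateError("k_deg + mu must be positive for both species")
    return k.k_syn_circ / (k.k_deg_circ + mu), k.k_syn_lin / (k.k_deg_lin + mu)


@dataclass
class StarvationDesign:
    """Piecewise-constant growth-rate schedule emulating starvation/recovery.

    ``boundaries`` are K+1 increasing times (hours); ``mus`` are K growth
    rates, one per interval [boundaries[i], boundaries[i+1]).
    """

    boundaries: np.ndarray
    mus: np.ndarray
    sample_times: np.ndarray
    replicates: int = 1

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.mus = np.asarray(self.mus, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.boundaries.size != self.mus.size + 1:
            raise ValueError("need one growth rate per schedule interval")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("schedule boundaries must be strictly increasing")
        if (self.mus < 0).any():
            raise ValueError("growth rates must be non-negative")
        if (self.sample_times < self.boundaries[0]).any() or (
            self.sample_times > self.boundaries[-1]
        ).any():
            raise ValueError("sample times outside schedule support")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _advance(c0: float, k_syn: float, a: float, dt: float) -> float:
    """Closed-form solution of dC/dt = k_syn - a*C over dt from C(0)=c0."""
    if a == 0.0:
        return c0 + k_syn * dt
    c_inf = k_syn / a
    return c_inf + (c0 - c_inf) * math.exp(-a * dt)


def simulate_timecourse(
    k: KineticParams,
    design: StarvationDesign,
    initial: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Exact piecewise-exponential trajectory of (circ, lin, circ-to-linear ratio).

    Initial condition defaults to the steady state at the first interval's mu.
    """
    if initial is None:
        initial = steady_state_abundance(k, float(design.mus[0]))
    circ0, lin0 = float(initial[0]), float(initial[1])

    # precompute species values at each boundary
    b = design.boundaries
    circ_b = [circ0]
    lin_b = [lin0]
    for i, mu in enumerate(design.mus):
        dt = b[i + 1] - b[i]
        circ_b.append(_advance(circ_b[-1], k.k_syn_circ, k.k_deg_circ + mu, dt))
        lin_b.append(_advance(lin_b[-1], k.k_syn_lin, k.k_deg_lin + mu, dt))

    rows = []
    for t in design.sample_times:
        seg = int(np.searchsorted(b, t, side="right") - 1)
        seg = min(seg, design.mus.size - 1)
        dt = t - b[seg]
        mu = float(design.mus[seg])
        circ = _advance(circ_b[seg], k.k_syn_circ, k.k_deg_circ + mu, dt)
        lin = _advance(lin_b[seg], k.k_syn_lin, k.k_deg_lin + mu, dt)
        rows.append({"time_h": float(t), "circ": circ, "lin": lin,
                     "circ_to_linear_ratio": circ_linear_ratio(circ, lin)})
    return pd.DataFrame(rows)


@dataclass
class CallerModel:
    """Per-caller detection probability and read-capture efficiency."""

    detect_p: float
    capture: float

    def __post_init__(self) -> None:
        if not (0 <= self.detect_p <= 1 and 0 < self.capture <= 1):
            raise ValueError("detect_p in [0,1], capture in (0,1] required")


@dataclass
class CohortDesign:
    """Design of one simulated cohort; defaults emulate the study conditions.

    Growth rates are in 1/h (doubling time ln2/mu); a plasma-cell mu of
    0.02/h corresponds to ~35 h doubling. Plasma-cell fraction of MM
    whole-marrow samples lies in [0.10, 0.90]; healthy controls carry at most
    2% plasma cells. Survival is exponential proportional hazards on the
    latent severity with administrative censoring at 120 months.
    """

    n_mm: int
    n_hc: int = 0
    mode: str = "whole_bm"  # whole_bm | purified_pc
    seed: int = 0
    n_genes: int = 260
    n_circ: int = 150
    severity_sd: float = 1.0
    mu_pc_base: float = 0.015
    mu_pc_slope: float = 0.5
    mu_other_base: float = 0.02
    mu_other_slope: float = 0.6
    mu_other_hc: float = 0.05
    pc_frac_base: float = 0.40
    pc_frac_slope: float = 0.8
    hazard_coef_gamma: float = 0.8
    baseline_hazard: float = 0.02  # events/month
    censor_admin_time: float = 120.0  # months
    dispersion_phi: float = 0.15
    libsize_mean: float = 3.0e5
    libsize_cv: float = 0.25
    caller_sensitivity: dict = field(
        default_factory=lambda: {
            CALLER_A: CallerModel(detect_p=0.95, capture=1.0),
            CALLER_B: CallerModel(detect_p=0.70, capture=0.6),
        }
    )
    db_coverage: float = 0.85
    ig_fraction: float = 0.25
    purity_low: float = 0.82
    purity_high: float = 0.995

    def __post_init__(self) -> None:
        if self.n_mm < 2:
            raise ValueError("n_mm must be >= 2")
        if self.mode not in ("whole_bm", "purified_pc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dispersion_phi <= 0:
            raise ValueError("dispersion_phi must be positive")
        if not 0 <= self.db_coverage <= 1:
            raise ValueError("db_coverage must lie in [0, 1]")


def _coupling(design: CohortDesign, s: float) -> tuple[float, float, float]:
    """Map latent severity to (mu_pc, mu_other, plasma fraction)."""
    mu_pc = design.mu_pc_base * math.exp(design.mu_pc_slope * s)
    mu_other = design.mu_other_base * math.exp(-design.mu_other_slope * s)
    base = design.pc_frac_base
    logit = math.log(base / (1 - base)) + design.pc_frac_slope * s
    frac01 = 1.0 / (1.0 + math.exp(-logit))
    p = 0.10 + 0.80 * frac01  # keeps MM whole-marrow fraction inside [0.10, 0.90]
    if not 0.10 <= p <= 0.90:
        raise ValueError("coupling produced plasma fraction outside [0.10, 0.90]")
    return mu_pc, mu_other, p


@dataclass
class FeatureUniverse:
    """Fixed per-cohort feature set: genes, circRNAs, kinetics, databases."""

    genes: pd.DataFrame  # index gene_id: length_bp, baseline, excluded_from_tpm, prolif, pc_specific, k_deg_lin
    circs: pd.DataFrame  # index circ_id str: host_gene, chrom, start, end, strand, k_syn_circ, k_deg_circ
    databases: dict[str, set[CircId]]


def _rng_for(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(counter,)))

MU_REF = 0.03  # reference growth rate scaling proliferation-gene expression


def build_features(design: CohortDesign) -> FeatureUniverse:
    """Deterministic feature universe derived from the design seed (stream 0)."""
    rng = _rng_for(design.seed, 0)
    signatures = load_signatures()
    prolif_genes = sorted(set().union(*[set(s.genes) for s in signatures.values()]) | {"MKI67"})
    hose_genes = set(signatures["hose"].genes)
    named = list(prolif_genes) + ["BCL2"] + list(IG_GENES)
    n_filler = max(design.n_genes - len(named), design.n_circ // 2)
    filler = [f"GENE{i:04d}" for i in range(1, n_filler + 1)]
    gene_ids = named + filler

    lengths = rng.integers(500, 5001, size=len(gene_ids))
    baseline = rng.lognormal(mean=3.0, sigma=0.8, size=len(gene_ids))
    k_deg_lin = rng.uniform(0.10, 0.35, size=len(gene_ids))
    genes = pd.DataFrame(
        {
            "length_bp": lengths,
            "baseline": baseline,
            "excluded_from_tpm": [g in IG_GENES for g in gene_ids],
            "prolif": [g in prolif_genes for g in gene_ids],
            "pc_specific_prolif": [g in hose_genes for g in gene_ids],
            "ig": [g in IG_GENES for g in gene_ids],
            "k_deg_lin": k_deg_lin,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # circRNA hosts: drawn from filler genes; most hosts yield one isoform
    n_hosts_needed = design.n_circ
    hosts: list[str] = []
    host_pool = list(filler)
    i = 0
    while len(hosts) < n_hosts_needed and i < len(host_pool):
        host = host_pool[i]
        n_iso = 1 + rng.poisson(0.25)
        hosts.extend([host] * n_iso)
        i += 1
    hosts = hosts[: design.n_circ]
    chroms = [f"chr{c}" for c in rng.integers(1, 23, size=len(hosts))]
    starts = rng.integers(1_000, 5_000_000, size=len(hosts))
    spans = rng.integers(200, 20_000, size=len(hosts))
    strands = np.where(rng.random(len(hosts)) < 0.5, "+", "-")
    circ_frac = rng.lognormal(mean=math.log(0.02), sigma=0.8, size=len(hosts))
    k_deg_circ = rng.uniform(0.002, 0.01, size=len(hosts))

    circ_rows = []
    seen: set[str] = set()
    for j, host in enumerate(hosts):
        cid = CircId(chroms[j], int(starts[j]), int(starts[j] + spans[j]), str(strands[j]))
        key = str(cid)
        if key in seen:  # vanishingly unlikely; keep identities unique
            continue
        seen.add(key)
        k_syn_lin = genes.loc[host, "baseline"] * genes.loc[host, "k_deg_lin"]
        circ_rows.append(
            {
                "circ_id": key,
                "host_gene": host,
                "chrom": cid.chrom,
                "start": cid.start,
                "end": cid.end,
                "strand": cid.strand,
                "k_syn_circ": float(circ_frac[j] * k_syn_lin),
                "k_deg_circ": float(k_deg_circ[j]),
            }
        )
    circs = pd.DataFrame(circ_rows).set_index("circ_id", drop=False)

    databases: dict[str, set[CircId]] = {name: set() for name in DB_NAMES}
    covered = rng.random(len(circs)) < design.db_coverage
    for j, key in enumerate(circs.index):
        if covered[j]:
            cid = CircId.from_string(key)
            n_db = 1 + int(rng.integers(0, len(DB_NAMES)))
            for name in rng.choice(DB_NAMES, size=n_db, replace=False):
                databases[str(name)].add(cid)
    return FeatureUniverse(genes=genes, circs=circs, databases=databases)


def _gene_profile(genes: pd.DataFrame, mu: float, cell: str) -> np.ndarray:
    """Relative per-cell abundance of linear genes in one cell type at growth mu."""
    base = genes["baseline"].to_numpy(dtype=float)
    kd = genes["k_deg_lin"].to_numpy(dtype=float)
    # linear kinetics: abundance = k_syn/(k_deg+mu), k_syn = baseline*k_deg
    abundance = base * kd / (kd + mu)
    prolif_factor = max(mu, 0.0015) / MU_REF
    abundance = np.where(genes["prolif"], abundance * prolif_factor, abundance)
    if cell != "plasma_cell":
        abundance = np.where(genes["ig"], base * 1e-3, abundance)
        abundance = np.where(genes["pc_specific_prolif"], abundance * 0.02, abundance)
    # plasma-cell immunoglobulin load is set by cell_type_profile (ig_fraction share)
    return abundance


def _circ_profile(circs: pd.DataFrame, mu: float) -> np.ndarray:
    return circs["k_syn_circ"].to_numpy() / (circs["k_deg_circ"].to_numpy() + mu)


@dataclass
class CellTypeProfile:
    """One cell type's growth rate and expected per-feature abundances."""

    name: str
    growth_rate_mu: float
    expr_baseline: pd.Series  # linear genes
    circ_abundance: pd.Series

    def __post_init__(self) -> None:
        if self.growth_rate_mu < 0:
            raise ValueError("growth rate must be non-negative")
        vals = self.expr_baseline.to_numpy()
        if (vals < 0).any() or not (vals > 0).any():
            raise ValueError("expr_baseline must be non-negative and not all zero")


def cell_type_profile(universe: FeatureUniverse, mu: float, cell: str,
                      ig_fraction: float = 0.25) -> CellTypeProfile:
    genes = universe.genes
    abundance = _gene_profile(genes, mu, cell)
    if cell == "plasma_cell":
        ig_mask = genes["ig"].to_numpy(dtype=bool)
        non_ig_total = abundance[~ig_mask].sum()
        total_ig = non_ig_total * ig_fraction / (1.0 - ig_fraction)
        abundance = abundance.copy()
        abundance[ig_mask] = total_ig / ig_mask.sum()
    circ = _circ_profile(universe.circs, mu)
    return CellTypeProfile(
        name=cell,
        growth_rate_mu=mu,
        expr_baseline=pd.Series(abundance, index=genes.index),
        circ_abundance=pd.Series(circ, index=universe.circs.index),
    )


@dataclass
class SimulatedCohort:
    """Count matrices, BSJ calls, metadata and ground truth for one cohort."""

    design: CohortDesign
    linear_counts: ExpressionMatrix
    bsj_calls: dict[str, list[BsjCall]]
    samples: list[SampleRecord]
    truth: dict
    databases: dict[str, set[CircId]]

    @property
    def metadata(self) -> pd.DataFrame:
        return samples_to_frame(self.samples)

    @property
    def all_calls(self) -> list[BsjCall]:
        return [c for calls in self.bsj_calls.values() for c in calls]

    def annotation_db(self) -> AnnotationDB:
        membership: dict[CircId, set[str]] = {}
        for name, ids in self.databases.items():
            for cid in ids:
                membership.setdefault(cid, set()).add(name)
        return AnnotationDB({cid: frozenset(v) for cid, v in membership.items()})


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with variance = mean + phi*mean^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        r = 1.0 / phi
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


JUNCTION_WINDOW_KB = 0.2  # effective junction capture window, kb equivalents


def simulate_cohort(design: CohortDesign) -> SimulatedCohort:
    """Draw one cohort: counts, per-caller BSJ calls, survival, truth.

    One RNG stream per sample, derived from the master seed by counter, makes
    the output byte-identical regardless of generation order.
    """
    if design.mode == "purified_pc" and design.n_hc > 0:
        raise ValueError("purified_pc cohorts have no healthy controls")
    universe = build_features(design)
    genes, circs = universe.genes, universe.circs
    gene_lengths_kb = genes["length_bp"].to_numpy() / 1000.0

    sample_records: list[SampleRecord] = []
    truth_samples: dict[str, dict] = {}
    linear_cols: dict[str, np.ndarray] = {}
    calls: dict[str, list[BsjCall]] = {CALLER_A: [], CALLER_B: []}
    sens_a = design.caller_sensitivity[CALLER_A]
    sens_b = design.caller_sensitivity[CALLER_B]

    roster = [("MM", i) for i in range(design.n_mm)] + [("HC", i) for i in range(design.n_hc)]
    for counter, (diagnosis, idx) in enumerate(roster, start=1):
        rng = _rng_for(design.seed, counter)
        sid = f"{'mm' if diagnosis == 'MM' else 'hc'}{idx + 1:03d}"
        if diagnosis == "MM":
            s = float(rng.normal(0.0, design.severity_sd))
            mu_pc, mu_other, p = _coupling(design, s)
        else:
            s = 0.0
            mu_pc = design.mu_pc_base
            mu_other = design.mu_other_hc
            p = float(rng.uniform(0.005, 0.02))

        pc = cell_type_profile(universe, mu_pc, "plasma_cell", design.ig_fraction)
        if design.mode == "whole_bm":
            other = cell_type_profile(universe, mu_other, "other_marrow", design.ig_fraction)
            gene_ab = p * pc.expr_baseline.to_numpy() + (1 - p) * other.expr_baseline.to_numpy()
            circ_ab = p * pc.circ_abundance.to_numpy() + (1 - p) * other.circ_abundance.to_numpy()
            purity = None
        else:
            gene_ab = pc.expr_baseline.to_numpy()
            circ_ab = pc.circ_abundance.to_numpy()
            purity = float(rng.uniform(design.purity_low, design.purity_high))

        # read-generating weights: genes scale with length, BSJ reads with a
        # fixed junction window so circ-vs-host read ratios track abundance
        gene_w = gene_ab * gene_lengths_kb
        circ_w = circ_ab * JUNCTION_WINDOW_KB
        host_idx = genes.index.get_indexer(circs["host_gene"])
        host_w = gene_ab[host_idx] * JUNCTION_WINDOW_KB
        denom = gene_w.sum()

        libsize = float(rng.lognormal(math.log(design.libsize_mean),
                                      design.libsize_cv))
        gene_mean = libsize * gene_w / denom
        circ_mean = libsize * circ_w / denom
        host_mean = libsize * host_w / denom

        linear_cols[sid] = _nb_draw(rng, gene_mean, design.dispersion_phi)
        circ_true = _nb_draw(rng, circ_mean, design.dispersion_phi)
        host_reads = _nb_draw(rng, host_mean, design.dispersion_phi)
        detect_a = rng.random(len(circs)) < sens_a.detect_p
        reads_a = rng.binomial(circ_true, sens_a.capture)
        detect_b = rng.random(len(circs)) < sens_b.detect_p
        reads_b = rng.binomial(reads_a, sens_b.capture)
        for j, key in enumerate(circs.index):
            if detect_a[j] and reads_a[j] > 0:
                calls[CALLER_A].append(
                    BsjCall(
                        circ_id=CircId.from_string(key),
                        sample_id=sid,
                        caller=CALLER_A,
                        junction_reads=int(reads_a[j]),
                        host_linear_reads=int(host_reads[j]),
                        host_gene=str(circs.iloc[j]["host_gene"]),
                    )
                )
                if detect_b[j] and reads_b[j] > 0:
                    calls[CALLER_B].append(
                        BsjCall(
                            circ_id=CircId.from_string(key),
                            sample_id=sid,
                            caller=CALLER_B,
                            junction_reads=int(reads_b[j]),
                        )
                    )

        hazard = design.baseline_hazard * math.exp(design.hazard_coef_gamma * s)
        t_event = float(rng.exponential(1.0 / hazard))
        t_event = max(t_event, 1e-3)
        os_months = min(t_event, design.censor_admin_time)
        event = int(t_event <= design.censor_admin_time)

        sample_records.append(
            SampleRecord(sid, design.mode, diagnosis, round(p, 6),
                         round(os_months, 6), event, purity)
        )
        truth_samples[sid] = {
            "s": s,
            "mu_pc": mu_pc,
            "mu_other": mu_other if design.mode == "whole_bm" else None,
            "pc_fraction": p,
            "libsize": libsize,
            "total_circ_steady": float(circ_ab.sum()),
        }

    order = [r.sample_id for r in sample_records]
    values = pd.DataFrame({sid: linear_cols[sid] for sid in order}, index=genes.index)
    feature_meta = pd.DataFrame(
        {
            "kind": "linear",
            "length_bp": genes["length_bp"],
            "excluded_from_tpm": genes["excluded_from_tpm"],
            "host_gene": genes.index,
        },
        index=genes.index,
    )
    linear = ExpressionMatrix(values=values, feature_meta=feature_meta)

    truth = {
        "design": {"mode": design.mode, "seed": design.seed, "n_mm": design.n_mm,
                   "n_hc": design.n_hc, "gamma": design.hazard_coef_gamma,
                   "dispersion_phi": design.dispersion_phi},
        "samples": truth_samples,
        "features": {
            key: {
                "host_gene": str(row["host_gene"]),
                "k_syn_circ": float(row["k_syn_circ"]),
                "k_deg_circ": float(row["k_deg_circ"]),
                "k_syn_lin": float(genes.loc[row["host_gene"], "baseline"]
                                   * genes.loc[row["host_gene"], "k_deg_lin"]),
                "k_deg_lin": float(genes.loc[row["host_gene"], "k_deg_lin"]),
                "in_db": sorted(name for name, ids in universe.databases.items()
                                if CircId.from_string(key) in ids),
            }
            for key, row in circs.iterrows()
        },
    }
    return SimulatedCohort(
        design=design,
        linear_counts=linear,
        bsj_calls=calls,
        samples=sample_records,
        truth=truth,
        databases=universe.databases,
    )


def write_cohort(cohort: SimulatedCohort, directory: Path | str, overwrite: bool = False) -> None:
    """Write a cohort to disk in the text formats the parsers read back.

    Layout: linear_counts.tsv, feature_annotation.tsv, sample_metadata.tsv,
    truth.json, bsj/<sample>__caller_{a,b}.{tsv,bed}, databases/<db>.tsv.
    """
    directory = Path(directory)
    targets = [directory / "linear_counts.tsv", directory / "feature_annotation.tsv",
               directory / "sample_metadata.tsv", directory / "truth.json"]
    if not overwrite:
        clash = [str(p) for p in targets if p.exists()]
        if clash:
            raise FileExistsError(f"refusing to overwrite: {clash}")
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "bsj").mkdir(exist_ok=True)
    (directory / "databases").mkdir(exist_ok=True)

    cohort.linear_counts.values.rename_axis("feature_id").to_csv(
        directory / "linear_counts.tsv", sep="\t")

    meta = cohort.linear_counts.feature_meta.copy()
    circ_meta = pd.DataFrame(
        {
            "kind": "circular",
            "length_bp": np.nan,
            "excluded_from_tpm": False,
            "host_gene": {k: v["host_gene"] for k, v in cohort.truth["features"].items()},
        }
    )
    pd.concat([meta, circ_meta]).rename_axis("feature_id").to_csv(
        directory / "feature_annotation.tsv", sep="\t")

    cohort.metadata.to_csv(directory / "sample_metadata.tsv", sep="\t", index=False)

    with open(directory / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)

    by_sample: dict[tuple[str, str], list[BsjCall]] = {}
    for caller, calls in cohort.bsj_calls.items():
        for call in calls:
            by_sample.setdefault((call.sample_id, caller), []).append(call)
    for record in cohort.samples:
        sid = record.sample_id
        a_calls = sorted(by_sample.get((sid, CALLER_A), []), key=lambda c: str(c.circ_id))
        with open(directory / "bsj" / f"{sid}__caller_a.tsv", "w") as fh:
            fh.write("\t".join(["circ_id", "chrom", "start", "end", "strand",
                                "junction_reads", "host_linear_reads", "host_gene"]) + "\n")
            for c in a_calls:
                fh.write("\t".join([str(c.circ_id), c.circ_id.chrom, str(c.circ_id.start),
                                    str(c.circ_id.end), c.circ_id.strand,
                                    str(c.junction_reads), str(c.host_linear_reads),
                                    c.host_gene]) + "\n")
        b_calls = sorted(by_sample.get((sid, CALLER_B), []), key=lambda c: str(c.circ_id))
        with open(directory / "bsj" / f"{sid}__caller_b.bed", "w") as fh:
            for c in b_calls:
                fh.write("\t".join([c.circ_id.chrom, str(c.circ_id.start - 1),
                                    str(c.circ_id.end), str(c.circ_id), str(c.junction_reads),
                                    c.circ_id.strand]) + "\n")

    for name in DB_NAMES:
        ids = sorted(cohort.databases.get(name, set()), key=str)
        with open(directory / "databases" / f"{name}.tsv", "w") as fh:
            fh.write("#coords=one-based\n")
            for cid in ids:
                fh.write("\t".join([cid.chrom, str(cid.start), str(cid.end),
                                    cid.strand, name]) + "\n")


def read_cohort(directory: Path | str):
    """Load a written cohort directory back into analysis-ready objects.

    Returns (linear ExpressionMatrix, list[BsjCall], AnnotationDB,
    metadata DataFrame, truth dict).
    """
    from .circconsensus import parse_bsj_table

    directory = Path(directory)
    values = pd.read_csv(directory / "linear_counts.tsv", sep="\t", index_col="feature_id")
    annot = pd.read_csv(directory / "feature_annotation.tsv", sep="\t", index_col="feature_id")
    linear_meta = annot[annot["kind"] == "linear"].loc[values.index]
    linear = ExpressionMatrix(values=values, feature_meta=linear_meta)

    calls: list[BsjCall] = []
    for path in sorted((directory / "bsj").glob("*__caller_a.tsv")):
        calls.extend(parse_bsj_table(path, CALLER_A))
    for path in sorted((directory / "bsj").glob("*__caller_b.bed")):
        calls.extend(parse_bsj_table(path, CALLER_B))

    db = AnnotationDB.from_tables(sorted((directory / "databases").glob("*.tsv")))
    metadata = pd.read_csv(directory / "sample_metadata.tsv", sep="\t",
                           index_col="sample_id").assign(
        sample_id=lambda f: f.index)
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return linear, calls, db, metadata, truth
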