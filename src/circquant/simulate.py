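"""Synthetic data generator with known ground truth.

Emulates the study design this package targets: 4 sample types (seedling,
root, leaf, flower) x 4 biological replicates, sequenced under two
protocols — R- (rRNA-depleted) and R+ (rRNA-depleted then RNase R-treated,
roughly half the depth, strongly circle-enriched) — with organ-dependent
rRNA and chloroplast read fractions, plus droplet-level ddPCR replicates
and linear-counterpart abundances.

The circRNA population mixes a small reproducible fraction (persistent
per-organ concentrations, lognormal across circRNAs with multiplicative
organ effects, optionally with planted organ-specific circles) with a large
stochastic fraction: one-off molecules that exist in exactly one (organ,
replicate) RNA isolate — and hence in both protocol libraries of that
replicate, since one isolate feeds both. RNase R loss acts per circRNA
species (survival Bernoulli), so a lost circle vanishes from every R+
library, mimicking hydrolysis-then-digestion.

Counts are Poisson around ``true_cp * capture_per_read * effective_reads``
(effective = total minus rRNA and chloroplast reads) with lognormal
replicate noise; the capture coefficient default makes 1 back-spliced read
correspond to ~5 cp/ug at the reference depth, so the conventional
10-normalized-read detection threshold matches a 50 cp/ug LoQ.

Identical configurations (including the seed) produce identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddpcr import MARKER_GENE_ID, cp_per_ug_to_lambda
from .model import ORGANS, CircCountMatrix, CircId, LibraryStats, LinearCountMatrix, SampleMeta
from .normalize import NormalizedMatrix, NormMethod

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_truth",
    "simulate_rnaseq",
    "simulate_ddpcr",
    "simulate_dilution_panel",
    "simulate_linear",
    "simulate_null_matrix",
    "simulate_dataset",
]


def _default_rrna_rminus():
    # per-organ (low, high) read fractions; roots lowest, leaves highest
    return {
        "seedling": (0.03, 0.06),
        "root": (0.006, 0.012),
        "leaf": (0.06, 0.0757),
        "flower": (0.015, 0.035),
    }


def _default_rrna_rplus():
    return {
        "seedling": (0.005, 0.015),
        "root": (0.0027, 0.006),
        "leaf": (0.01, 0.02),
        "flower": (0.02, 0.0318),
    }


def _default_chloroplast_frac():
    # photosynthetic tissues carry a large chloroplast read load
    return {
        "seedling": (0.15, 0.25),
        "root": (0.005, 0.02),
        "leaf": (0.20, 0.30),
        "flower": (0.05, 0.10),
    }


@dataclass
class SimConfig:
    """Generator parameters. Defaults encode the emulated study conditions."""

    seed: int = 0
    organs: tuple = ORGANS
    n_reps: int = 4
    n_circ_total: int = 2000
    fraction_reproducible: float = 0.05
    fraction_chloroplast: float = 0.05
    fraction_intergenic: float = 0.10

    # reproducible abundance law, cp/ug on the natural-log scale
    log_mean_cp: float = math.log(3.0)
    log_sigma_cp: float = 1.5
    organ_effect_sigma: float = 0.4
    # stochastic one-off molecules
    stochastic_log_mean: float = math.log(15.0)
    stochastic_log_sigma: float = 1.0
    # RNA-seq biological replicate noise (lognormal sigma, ln scale)
    replicate_sigma: float = 0.3

    # planted organ-specific circles (drawn from the reproducible pool)
    planted_per_organ: int = 5
    planted_base_cp: float = 15.0
    planted_fold: float = 8.0

    # library composition
    mean_depth: float = 60_292_166.0
    depth_jitter: float = 0.10
    rplus_depth_factor: float = 0.43
    rrna_frac_rminus: dict = field(default_factory=_default_rrna_rminus)
    rrna_frac_rplus: dict = field(default_factory=_default_rrna_rplus)
    chloroplast_frac: dict = field(default_factory=_default_chloroplast_frac)
    marker_frac: float = 5e-4
    marker_noise_sigma: float = 0.10
    # expected back-spliced reads per effective read per cp/ug
    capture_per_read: float = 4e-9

    # RNase R protocol effects
    rplus_enrichment: float = 10.0
    rplus_survival: float = 0.9

    # ddPCR
    ddpcr_droplets: int = 15_000
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    rna_mass_ug: float = 0.05
    ddpcr_sigma: float = 0.15
    ddpcr_bio_reps: int = 3
    marker_technical_reps: int = 4
    marker_cp_per_ug: float = 2e5

    # linear counterparts
    circ_linear_corr: float = 0.46
    linear_log_mean: float = math.log(2000.0)
    linear_log_sigma: float = 1.2

    def __post_init__(self) -> None:
        for name in ("fraction_reproducible", "fraction_chloroplast",
                     "fraction_intergenic", "rplus_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 < self.circ_linear_corr < 1.0:
            raise ValueError("circ_linear_corr must be in (-1, 1)")
        for name in ("rplus_enrichment", "capture_per_read", "mean_depth",
                     "planted_fold", "planted_base_cp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_repr = round(self.fraction_reproducible * self.n_circ_total)
        if self.planted_per_organ * len(self.organs) > n_repr:
            raise ValueError(
                "planted organ-specific circRNAs exceed the reproducible pool; "
                "raise fraction_reproducible or lower planted_per_organ"
            )

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth: identities, per-organ concentrations, planted structure."""

    config: SimConfig
    circ_ids: list
    parent_gene: dict
    reproducible_ids: list
    true_cp: pd.DataFrame  # reproducible circRNAs x organs, cp/ug
    stochastic_events: pd.DataFrame  # circ_id, organ, replicate, cp_per_ug
    planted: dict  # organ -> list of circ id strings

    @property
    def id_strings(self):
        return [str(c) for c in self.circ_ids]

    @property
    def chloroplast_ids(self):
        return [str(c) for c in self.circ_ids if c.is_organelle()]

    def cp_for_sample(self, organ: str, replicate: int) -> pd.Series:
        """True cp/ug of every circRNA in one biological replicate's RNA."""
        cp = pd.Series(0.0, index=self.id_strings)
        cp.loc[self.true_cp.index] = self.true_cp[organ]
        ev = self.stochastic_events
        hit = ev[(ev["organ"] == organ) & (ev["replicate"] == replicate)]
        cp.loc[hit["circ_id"].to_numpy()] = hit["cp_per_ug"].to_numpy()
        return cp


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def generate_truth(config: SimConfig) -> SimTruth:
    """Draw circRNA identities and true per-organ concentrations."""
    rng = _rng(config, 1)
    n = config.n_circ_total
    n_chloro = round(config.fraction_chloroplast * n)
    circ_ids = []
    seen = set()
    while len(circ_ids) < n:
        if len(circ_ids) < n_chloro:
            chrom = "chloroplast"
            start = int(rng.integers(1, 150_000))
        else:
            chrom = str(rng.integers(1, 6))
            start = int(rng.integers(1, 30_000_000))
        end = start + int(rng.integers(100, 2000))
        cid = CircId(chrom, start, end)
        if str(cid) in seen:
            continue
        seen.add(str(cid))
        circ_ids.append(cid)

    parent_gene = {}
    for i, cid in enumerate(circ_ids):
        if rng.random() < config.fraction_intergenic:
            parent_gene[str(cid)] = None
        elif cid.chrom == "chloroplast":
            parent_gene[str(cid)] = f"ATCG{i:05d}"
        else:
            parent_gene[str(cid)] = f"AT{cid.chrom}G{i:05d}"

    n_repr = round(config.fraction_reproducible * n)
    perm = rng.permutation(n)
    repr_idx = sorted(perm[:n_repr])
    repr_ids = [str(circ_ids[i]) for i in repr_idx]
    stoch_ids = [str(circ_ids[i]) for i in sorted(perm[n_repr:])]

    organs = list(config.organs)
    # planted organ-specific circles first, then the free reproducible pool
    planted: dict = {o: [] for o in organs}
    pool = list(repr_ids)
    true_cp = pd.DataFrame(0.0, index=repr_ids, columns=organs)
    k = 0
    for organ in organs:
        for _ in range(config.planted_per_organ):
            cid = pool[k]
            k += 1
            planted[organ].append(cid)
            for o in organs:
                true_cp.loc[cid, o] = config.planted_base_cp * (
                    config.planted_fold if o == organ else 1.0
                )
    free = pool[k:]
    if free:
        base = np.exp(rng.normal(config.log_mean_cp, config.log_sigma_cp, size=len(free)))
        effects = np.exp(
            rng.normal(0.0, config.organ_effect_sigma, size=(len(free), len(organs)))
        )
        true_cp.loc[free, :] = base[:, None] * effects

    events = pd.DataFrame(
        {
            "circ_id": stoch_ids,
            "organ": rng.choice(organs, size=len(stoch_ids)),
            "replicate": rng.integers(1, config.n_reps + 1, size=len(stoch_ids)),
            "cp_per_ug": np.exp(
                rng.normal(config.stochastic_log_mean, config.stochastic_log_sigma,
                           size=len(stoch_ids))
            ),
        }
    )
    return SimTruth(
        config=config,
        circ_ids=circ_ids,
        parent_gene=parent_gene,
        reproducible_ids=repr_ids,
        true_cp=true_cp,
        stochastic_events=events,
        planted=planted,
    )


def _uniform_in(rng, bounds) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi))


def simulate_rnaseq(truth: SimTruth, protocols=("R-", "R+")) -> dict:
    """Back-spliced count matrices and library statistics per protocol.

    Returns ``{protocol: (CircCountMatrix, LibraryStats)}``. R+ libraries
    are shallower by ``rplus_depth_factor``, circle counts are multiplied by
    ``rplus_enrichment`` and by a per-species survival Bernoulli; survival
    failure zeroes the circRNA in every R+ replicate.
    """
    config = truth.config
    rng = _rng(config, 2)
    survival = rng.random(len(truth.circ_ids)) < config.rplus_survival
    chloro = np.array([c.is_organelle() for c in truth.circ_ids])
    id_strings = truth.id_strings

    out = {}
    for protocol in protocols:
        rplus = protocol == "R+"
        samples = []
        count_cols = {}
        stat_rows = {}
        for organ in config.organs:
            rrna_bounds = (config.rrna_frac_rplus if rplus else config.rrna_frac_rminus)[organ]
            chl_bounds = config.chloroplast_frac[organ]
            for rep in range(1, config.n_reps + 1):
                depth = config.mean_depth * (config.rplus_depth_factor if rplus else 1.0)
                t = depth * (1.0 + rng.uniform(-config.depth_jitter, config.depth_jitter))
                r = t * _uniform_in(rng, rrna_bounds)
                p = t * _uniform_in(rng, chl_bounds)
                t, r, p = round(t), round(r), round(p)
                t_eff = t - r - p
                a = round(
                    config.marker_frac * t_eff
                    * math.exp(rng.normal(0.0, config.marker_noise_sigma))
                )
                cp = truth.cp_for_sample(organ, rep).to_numpy()
                noise = np.exp(rng.normal(0.0, config.replicate_sigma, size=len(cp)))
                lam = cp * noise * config.capture_per_read * t_eff
                if rplus:
                    lam = lam * config.rplus_enrichment * survival
                counts = rng.poisson(lam)
                sid = f"{organ}_r{rep}_{protocol}"
                samples.append(SampleMeta(sid, organ, rep, protocol))
                count_cols[sid] = counts
                b = int(counts.sum())
                b_excl = int(counts[~chloro].sum())
                stat_rows[sid] = {
                    "total_reads": float(t),
                    "rrna_reads": float(r),
                    "chloroplast_reads": float(p),
                    "marker_reads": float(a),
                    "backspliced_reads": float(b),
                    "backspliced_reads_excl": float(b_excl),
                }
        counts_df = pd.DataFrame(count_cols, index=id_strings)
        support = {cid: frozenset({"ciri2", "find_circ"}) for cid in id_strings}
        matrix = CircCountMatrix(
            circ_ids=list(truth.circ_ids), samples=samples, counts=counts_df,
            caller_support=support,
        )
        stats = LibraryStats(pd.DataFrame(stat_rows).T)
        out[protocol] = (matrix, stats)
    return out


def _droplet_measurement(rng, config: SimConfig, cp: float):
    lam = cp_per_ug_to_lambda(
        cp, config.droplet_volume_nl, config.reaction_volume_ul, config.rna_mass_ug
    )
    p = 1.0 - math.exp(-lam)
    if p > 0.999:
        warnings.warn(
            f"ddPCR saturation: occupancy {p:.4f} at {cp:.3g} cp/ug", stacklevel=3
        )
    return int(rng.binomial(config.ddpcr_droplets, p))


def simulate_ddpcr(truth: SimTruth, targets) -> pd.DataFrame:
    """Droplet-level ddPCR assays for selected reproducible circRNAs.

    Per target and organ, ``ddpcr_bio_reps`` biological replicates are
    measured; replicate-level lognormal noise perturbs the true cp/ug, then
    positive droplets are drawn Binomial(n_total, 1 - exp(-lambda)). The
    reference-gene assay (4 technical repeats per biological replicate) is
    generated alongside, tagged ``is_marker``.
    """
    config = truth.config
    rng = _rng(config, 3)
    rows = []
    for target in targets:
        target = str(target)
        if target not in truth.true_cp.index:
            raise ValueError(f"target {target} is not a reproducible circRNA in the truth")
        for organ in config.organs:
            true = float(truth.true_cp.loc[target, organ])
            for rep in range(1, config.ddpcr_bio_reps + 1):
                cp = true * math.exp(rng.normal(0.0, config.ddpcr_sigma))
                n_pos = _droplet_measurement(rng, config, cp) if true > 0 else 0
                rows.append(
                    {
                        "target": target, "organ": organ, "replicate": rep,
                        "technical_rep": 1, "n_pos": n_pos,
                        "n_total": config.ddpcr_droplets, "is_marker": False,
                    }
                )
    for organ in config.organs:
        for rep in range(1, config.ddpcr_bio_reps + 1):
            for tech in range(1, config.marker_technical_reps + 1):
                cp = config.marker_cp_per_ug * math.exp(rng.normal(0.0, config.ddpcr_sigma))
                rows.append(
                    {
                        "target": MARKER_GENE_ID, "organ": organ, "replicate": rep,
                        "technical_rep": tech, "n_pos": _droplet_measurement(rng, config, cp),
                        "n_total": config.ddpcr_droplets, "is_marker": True,
                    }
                )
    return pd.DataFrame(rows)


def simulate_dilution_panel(config: SimConfig,
                            concentrations=(10.0, 30.0, 50.0, 100.0, 300.0),
                            n_replicates: int = 8) -> pd.DataFrame:
    """Droplet assays for a known dilution series (LoQ calibration).

    One synthetic target per true concentration, measured ``n_replicates``
    times with the configured replicate noise and droplet statistics. More
    replicates than the 3 of the biological assay are used because the
    sample CV of 3 near-zero droplet counts is too unstable to define a
    threshold.
    """
    rng = _rng(config, 4)
    rows = []
    for true in concentrations:
        target = f"panel_{true:g}"
        for rep in range(1, n_replicates + 1):
            cp = true * math.exp(rng.normal(0.0, config.ddpcr_sigma))
            rows.append(
                {
                    "target": target, "organ": "panel", "replicate": rep,
                    "true_cp_per_ug": true, "n_pos": _droplet_measurement(rng, config, cp),
                    "n_total": config.ddpcr_droplets, "is_marker": False,
                }
            )
    return pd.DataFrame(rows)


def simulate_linear(truth: SimTruth) -> LinearCountMatrix:
    """Per-organ linear-counterpart abundances for parent genes.

    The configured ``circ_linear_corr`` is the target correlation on the raw
    abundance scale (what a Pearson correlation of abundances measures). A
    bivariate lognormal attenuates correlation when exponentiated, so the
    log-scale correlation is obtained by inverting
    ``r = (exp(rho * sx * sy) - 1) / sqrt((exp(sx^2)-1)(exp(sy^2)-1))``.
    Intergenic circRNAs have no linear partner and are absent from the
    output.
    """
    config = truth.config
    rng = _rng(config, 5)
    organs = list(config.organs)
    genes, rows = [], []
    for cid in truth.reproducible_ids:
        gene = truth.parent_gene[cid]
        if gene is None:
            continue
        genes.append(gene)
        rows.append(truth.true_cp.loc[cid, organs].to_numpy(dtype=float))
    circ = np.asarray(rows)
    logc = np.log(np.maximum(circ, 1e-12))
    sx = float(np.std(logc))
    sy = config.linear_log_sigma
    r = config.circ_linear_corr
    arg = 1.0 + r * math.sqrt(math.expm1(sx ** 2) * math.expm1(sy ** 2))
    if arg <= 0:
        raise ValueError("circ_linear_corr too negative for the configured variances")
    rho = math.log(arg) / (sx * sy)
    if abs(rho) >= 1:
        raise ValueError(
            f"target raw-scale correlation {r} infeasible at these variances "
            f"(requires log-scale correlation {rho:.3f})"
        )
    z = (logc - logc.mean()) / sx
    eps = rng.normal(size=z.shape)
    logl = config.linear_log_mean + sy * (rho * z + math.sqrt(1 - rho ** 2) * eps)
    table = pd.DataFrame(np.exp(logl), index=genes, columns=organs)
    return LinearCountMatrix(abundances=table, method=None)


def simulate_null_matrix(n_circ: int = 2000, n_reps: int = 4,
                         organs=("organ_a", "organ_b"), log_mean: float = math.log(50.0),
                         sigma: float = 0.3, seed: int = 0) -> NormalizedMatrix:
    """Replicate matrices with NO organ effect (type-I error simulations).

    Every value is drawn from the same lognormal for all organs, so any
    significant differential call is a false positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 6)))
    samples = [
        SampleMeta(f"{o}_r{r}_R-", o, r, "R-")
        for o in organs for r in range(1, n_reps + 1)
    ]
    values = np.exp(rng.normal(log_mean, sigma, size=(n_circ, len(samples))))
    ids = [f"null:{i + 1}-{i + 2}" for i in range(n_circ)]
    df = pd.DataFrame(values, index=ids, columns=[s.sample_id for s in samples])
    return NormalizedMatrix(values=df, samples=samples,
                            method=NormMethod.library_size, scale=1.0)


def simulate_dataset(config: SimConfig, ddpcr_targets: int = 8):
    """Full bundle: truth, RNA-seq per protocol, ddPCR assays, linear matrix.

    ``ddpcr_targets`` reproducible circRNAs with the highest overall true
    abundance are assayed by ddPCR (mirroring a validation panel of
    well-expressed circles).
    """
    truth = generate_truth(config)
    rnaseq = simulate_rnaseq(truth)
    ranked = truth.true_cp.mean(axis=1).sort_values(ascending=False)
    targets = list(ranked.index[:ddpcr_targets])
    assays = simulate_ddpcr(truth, targets)
    linear = simulate_linear(truth)
    return truth, rnaseq, assays, linear
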