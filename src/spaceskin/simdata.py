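"""Multi-mission synthetic RNA-seq count generator with planted effects.

The generator emulates the rodent flight-vs-ground study design: three
missions partitioned into ten data subsets by diet, skin site, strain and
flight duration. Counts are negative-binomial draws with sample-specific
size factors and a mean–dispersion trend α(μ) = a0/μ + a1 (Var = μ + αμ²).
Four kinds of effects can be planted, and every planted effect is recorded
in a :class:`TruthTable` so downstream recovery can be measured:

* per-subset differential expression (a log2 fold change applied to the
  flight group of chosen subsets, including cross-mission genes planted in
  subsets of two or more missions),
* two-gene synergies — pairs whose latent log-expression relates to the
  flight label only through the product rule Bernoulli(σ(c·z_a·z_b)), so
  each gene is marginally non-predictive,
* co-expressed gene modules driven by a shared Gaussian latent factor on
  the log-mean scale,
* gene sets enriched for planted DE genes (fixtures for over-representation
  and rank-enrichment recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import SeedStream, ValidationError
from .io import CONDITIONS

__all__ = [
    "Subset", "StudyDesign", "SimulationParams",
    "DEEffect", "SynergyEffect", "ModuleEffect", "EffectSpec", "TruthTable",
    "make_design", "sample_effects", "simulate_counts", "plant_genesets",
    "simulate_synergy_dataset",
]


# ---------------------------------------------------------------------------
# design

@dataclass(frozen=True)
class Subset:
    subset_id: str
    mission: str
    factors: dict = field(default_factory=dict)

    def __hash__(self):  # factors dict excluded
        return hash((self.subset_id, self.mission))


@dataclass
class StudyDesign:
    missions: list[str]
    subsets: list[Subset]
    replicates_per_group: int = 6

    def __post_init__(self):
        ids = [s.subset_id for s in self.subsets]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate subset_id {dup!r}")
        for s in self.subsets:
            if s.mission not in self.missions:
                raise ValidationError(
                    f"subset {s.subset_id!r} references unknown mission "
                    f"{s.mission!r}"
                )
        if self.replicates_per_group < 2:
            raise ValidationError(
                "each condition group needs at least 2 replicates, got "
                f"{self.replicates_per_group}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.subsets) * 2 * self.replicates_per_group

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subsets:
            for cond in CONDITIONS:
                for r in range(1, self.replicates_per_group + 1):
                    rows.append({
                        "sample_id": f"{s.subset_id}_{cond}_{r}",
                        "mission": s.mission,
                        "subset_id": s.subset_id,
                        "condition": cond,
                        **{f"factor_{k}": v for k, v in s.factors.items()},
                    })
        return pd.DataFrame(rows)

    def subset_missions(self) -> dict[str, str]:
        return {s.subset_id: s.mission for s in self.subsets}


def make_design(preset: str | None = "paper-like", *,
                missions: list[str] | None = None,
                subsets: list[Subset] | None = None,
                replicates_per_group: int = 6) -> StudyDesign:
    """Build a :class:`StudyDesign`, either from the ``"paper-like"`` preset
    (3 missions, 10 flight-vs-ground subsets crossing diet, skin site,
    strain and duration) or from an explicit mission/subset specification.
    """
    if preset is None:
        if missions is None or subsets is None:
            raise ValidationError(
                "explicit designs need both missions and subsets"
            )
        return StudyDesign(missions, subsets, replicates_per_group)
    if preset != "paper-like":
        raise ValidationError(f"unknown design preset {preset!r}")
    subsets = []
    for diet in ("standard", "supplemented"):
        for site in ("dorsal", "femoral"):
            subsets.append(Subset(f"M1_{diet}_{site}", "mission1",
                                  {"diet": diet, "site": site}))
    for site in ("dorsal", "femoral"):
        subsets.append(Subset(f"M2_{site}", "mission2", {"site": site}))
    for strain in ("strainA", "strainB"):
        for duration in ("25d", "75d"):
            subsets.append(Subset(f"M3_{strain}_{duration}", "mission3",
                                  {"strain": strain, "duration": duration}))
    return StudyDesign(["mission1", "mission2", "mission3"], subsets,
                       replicates_per_group)


# ---------------------------------------------------------------------------
# parameters and effects

@dataclass
class SimulationParams:
    """NB generative parameters.

    Baseline natural-log means are Normal(log_mean_loc, log_mean_scale);
    gene dispersion follows the trend α(μ) = a0/μ + a1; size factors are
    log-uniform on [size_factor_low, size_factor_high].
    """

    n_genes: int = 2000
    log_mean_loc: float = 4.0
    log_mean_scale: float = 1.5
    dispersion_a0: float = 0.01
    dispersion_a1: float = 0.1
    size_factor_low: float = 0.5
    size_factor_high: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValidationError("dispersion coefficients must be >= 0")
        if self.dispersion_a0 == 0 and self.dispersion_a1 == 0:
            raise ValidationError("dispersion trend cannot be identically 0")
        if not (0 < self.size_factor_low <= self.size_factor_high):
            raise ValidationError("need 0 < size_factor_low <= size_factor_high")


@dataclass(frozen=True)
class DEEffect:
    gene: str
    subset_id: str
    lfc: float  # log2 fold change, flight vs ground


@dataclass(frozen=True)
class SynergyEffect:
    gene_a: str
    gene_b: str
    rule: str = "product"
    coeff: float = 3.0
    scale: float = 1.0  # log2 sd of the latent expression offsets


@dataclass(frozen=True)
class ModuleEffect:
    module_id: str
    genes: tuple
    loading: float = 1.5


@dataclass
class EffectSpec:
    de: list = field(default_factory=list)
    synergies: list = field(default_factory=list)
    modules: list = field(default_factory=list)


@dataclass
class TruthTable:
    """Ground-truth record of every planted effect in a simulation."""

    genes: list
    subset_missions: dict
    de: list = field(default_factory=list)
    synergies: list = field(default_factory=list)
    modules: list = field(default_factory=list)
    enriched_sets: list = field(default_factory=list)  # (set name, DE overlap)

    def de_genes(self, subset_id: str | None = None) -> set:
        if subset_id is None:
            return {e.gene for e in self.de}
        return {e.gene for e in self.de if e.subset_id == subset_id}

    def cross_mission_genes(self, min_missions: int = 2) -> set:
        per_gene: dict[str, set] = {}
        for e in self.de:
            per_gene.setdefault(e.gene, set()).add(
                self.subset_missions[e.subset_id])
        return {g for g, m in per_gene.items() if len(m) >= min_missions}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"effect": "de", "gene": e.gene, "partner": "",
                 "context": e.subset_id, "value": e.lfc} for e in self.de]
        rows += [{"effect": "synergy", "gene": e.gene_a, "partner": e.gene_b,
                  "context": e.rule, "value": e.coeff} for e in self.synergies]
        rows += [{"effect": "module", "gene": g, "partner": "",
                  "context": m.module_id, "value": m.loading}
                 for m in self.modules for g in m.genes]
        rows += [{"effect": "enriched_set", "gene": g, "partner": "",
                  "context": name, "value": math.nan}
                 for name, overlap in self.enriched_sets for g in overlap]
        return pd.DataFrame(rows,
                            columns=["effect", "gene", "partner", "context",
                                     "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def sample_effects(design: StudyDesign, params: SimulationParams, *,
                   n_subset_de: int = 20, n_cross_mission: int = 20,
                   lfc: float = 2.0, n_modules: int = 0, module_size: int = 60,
                   module_loading: float = 1.5, n_synergy_pairs: int = 0,
                   synergy_coeff: float = 3.0, seed: int = 0) -> EffectSpec:
    """Draw a concrete random effect specification for a design.

    ``n_subset_de`` genes are planted per subset (subset-private), and
    ``n_cross_mission`` genes are planted in one subset of every mission.
    Effect signs alternate so both directions occur. Genes are disjoint
    across effect kinds.
    """
    rng = np.random.default_rng([int(seed), 9])
    genes = _gene_names(params.n_genes)
    needed = (n_subset_de * len(design.subsets) + n_cross_mission
              + n_modules * module_size + 2 * n_synergy_pairs)
    if needed > params.n_genes:
        raise ValidationError(
            f"effects need {needed} genes but n_genes={params.n_genes}"
        )
    picks = rng.choice(params.n_genes, size=needed, replace=False)
    it = iter(picks)
    spec = EffectSpec()
    sign = 1
    for s in design.subsets:
        for _ in range(n_subset_de):
            spec.de.append(DEEffect(genes[next(it)], s.subset_id, sign * lfc))
            sign = -sign
    first_subsets = {}
    for s in design.subsets:
        first_subsets.setdefault(s.mission, s.subset_id)
    for _ in range(n_cross_mission):
        g = genes[next(it)]
        for subset_id in first_subsets.values():
            spec.de.append(DEEffect(g, subset_id, sign * lfc))
        sign = -sign
    for m in range(n_modules):
        members = tuple(genes[next(it)] for _ in range(module_size))
        spec.modules.append(ModuleEffect(f"module{m}", members,
                                         module_loading))
    for _ in range(n_synergy_pairs):
        spec.synergies.append(SynergyEffect(genes[next(it)], genes[next(it)],
                                            coeff=synergy_coeff))
    return spec


# ---------------------------------------------------------------------------
# simulation

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB draws with Var = μ + αμ² (gamma–Poisson mixture); α→0 is Poisson."""
    alpha = np.broadcast_to(alpha, mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_mask = alpha < 1e-12
    if poisson_mask.any():
        out[poisson_mask] = rng.poisson(mean[poisson_mask])
    nb = ~poisson_mask
    if nb.any():
        shape = 1.0 / alpha[nb]
        lam = rng.gamma(shape, alpha[nb] * mean[nb])
        out[nb] = rng.poisson(lam)
    return out


def _conditional_synergy_latents(rng: np.random.Generator, labels: np.ndarray,
                                 coeff: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample (z_a, z_b) ~ N(0,1)² conditioned on the flight label under the
    rule P(flight | z) = σ(coeff·z_a·z_b), by rejection."""
    n = labels.size
    za = np.empty(n)
    zb = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        prop_a = rng.standard_normal(pending.size)
        prop_b = rng.standard_normal(pending.size)
        p_flight = _sigmoid(coeff * prop_a * prop_b)
        accept_p = np.where(labels[pending] == 1, p_flight, 1.0 - p_flight)
        accepted = rng.random(pending.size) < accept_p
        idx = pending[accepted]
        za[idx] = prop_a[accepted]
        zb[idx] = prop_b[accepted]
        pending = pending[~accepted]
    return za, zb


def simulate_counts(design: StudyDesign, params: SimulationParams,
                    effects: EffectSpec | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate a counts matrix for a study design.

    Returns ``(counts, samples, truth)``: the gene×sample integer matrix,
    the sample metadata table, and the truth record of planted effects.
    Counts for gene g, sample j are NB with mean sf_j·μ_gj and variance
    μ + α(μ_g)μ², where μ_gj applies the planted log2 offsets (DE in flight
    groups, module latent factors, synergy latents) to the gene baseline.
    Identical inputs (including the seed in ``params``) reproduce the matrix
    bit for bit.
    """
    effects = effects or EffectSpec()
    genes = _gene_names(params.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    de_genes = {e.gene for e in effects.de}
    for syn in effects.synergies:
        for g in (syn.gene_a, syn.gene_b):
            if g in de_genes:
                raise ValidationError(
                    f"synergy gene {g!r} also carries planted DE; synergy "
                    "genes must have zero marginal effect"
                )
    for eff in effects.de:
        if eff.gene not in gene_index:
            raise ValidationError(f"unknown gene {eff.gene!r} in DE effects")
        if eff.subset_id not in {s.subset_id for s in design.subsets}:
            raise ValidationError(
                f"unknown subset {eff.subset_id!r} in DE effects"
            )

    stream = SeedStream(params.seed)
    rng_baseline = stream.spawn()
    rng_sf = stream.spawn()
    rng_latent = stream.spawn()
    rng_synergy = stream.spawn()
    rng_counts = stream.spawn()

    samples = design.sample_table()
    n_samples = len(samples)
    flight = (samples["condition"] == "flight").to_numpy()

    log_mu = rng_baseline.normal(params.log_mean_loc, params.log_mean_scale,
                                 size=params.n_genes)
    mu = np.exp(log_mu)
    alpha = params.dispersion_a0 / mu + params.dispersion_a1

    size_factors = np.exp(rng_sf.uniform(np.log(params.size_factor_low),
                                         np.log(params.size_factor_high),
                                         size=n_samples))

    # planted log2 offsets
    offsets = np.zeros((params.n_genes, n_samples))
    subset_of = samples["subset_id"].to_numpy()
    for eff in effects.de:
        cols = (subset_of == eff.subset_id) & flight
        offsets[gene_index[eff.gene], cols] += eff.lfc
    for mod in effects.modules:
        latent = rng_latent.standard_normal(n_samples)
        for g in mod.genes:
            offsets[gene_index[g], :] += mod.loading * latent
    for syn in effects.synergies:
        za, zb = _conditional_synergy_latents(
            rng_synergy, flight.astype(int), syn.coeff)
        offsets[gene_index[syn.gene_a], :] += syn.scale * za
        offsets[gene_index[syn.gene_b], :] += syn.scale * zb

    mean = size_factors[None, :] * mu[:, None] * np.exp2(offsets)
    counts = _nb_draw(rng_counts, mean, alpha[:, None])

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples["sample_id"].to_numpy())
    samples = samples.copy()
    samples["size_factor_true"] = size_factors
    truth = TruthTable(genes=genes, subset_missions=design.subset_missions(),
                       de=list(effects.de), synergies=list(effects.synergies),
                       modules=list(effects.modules))
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# gene sets over the truth

def plant_genesets(truth: TruthTable, n_sets: int = 50, set_size: int = 30,
                   enrichment_fraction: float = 0.8, n_enriched: int = 5,
                   seed: int = 0) -> dict[str, tuple[str, list[str]]]:
    """Build a gene-set collection over the simulated universe.

    The first ``n_enriched`` sets draw ``round(enrichment_fraction ×
    set_size)`` members from planted DE genes and the rest from non-DE
    genes; remaining sets are drawn uniformly from non-DE genes. The planted
    overlap is appended to ``truth.enriched_sets``.
    """
    if not (0.0 <= enrichment_fraction <= 1.0):
        raise ValidationError(
            f"enrichment_fraction must be in [0, 1], got {enrichment_fraction}"
        )
    if set_size > len(truth.genes):
        raise ValidationError("set_size exceeds the gene universe")
    if n_enriched > n_sets:
        raise ValidationError("n_enriched cannot exceed n_sets")
    rng = np.random.default_rng([int(seed), 77])
    de = sorted(truth.de_genes())
    non_de = [g for g in truth.genes if g not in set(de)]
    n_from_de = round(enrichment_fraction * set_size)
    if n_from_de > len(de):
        raise ValidationError(
            f"enriched sets need {n_from_de} DE genes but only {len(de)} "
            "are planted"
        )
    collection: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_sets):
        name = f"SET_{i:03d}"
        if i < n_enriched:
            members = list(rng.choice(de, size=n_from_de, replace=False))
            members += list(rng.choice(non_de, size=set_size - n_from_de,
                                       replace=False))
            truth.enriched_sets.append((name, list(members[:n_from_de])))
            desc = "planted_enriched"
        else:
            members = list(rng.choice(non_de, size=set_size, replace=False))
            desc = "background"
        collection[name] = (desc, members)
    return collection


def plant_regulator_kb(truth: TruthTable, subset_id: str,
                       n_targets: int = 20, n_scrambled: int = 1,
                       n_background: int = 5, background_targets: int = 20,
                       seed: int = 0) -> pd.DataFrame:
    """Build a synthetic signed regulator→target knowledge base.

    ``REG_ACT`` has ``n_targets`` targets drawn from the genes planted DE in
    ``subset_id`` with edge signs matching the planted fold-change signs (so
    it should be called activated there); ``REG_SCRAMBLED*`` regulators use
    the same kind of targets but with the edge sign flipped for exactly half
    of them, balancing consistent against inconsistent targets so the
    activation z sits near zero; background regulators target non-DE genes
    with random signs.
    """
    rng = np.random.default_rng([int(seed), 55])
    de_in_subset = [e for e in truth.de if e.subset_id == subset_id]
    if len(de_in_subset) < n_targets:
        raise ValidationError(
            f"subset {subset_id!r} has only {len(de_in_subset)} planted DE "
            f"genes; need {n_targets}"
        )
    rows = []
    picks = rng.choice(len(de_in_subset), size=n_targets, replace=False)
    for i in picks:
        e = de_in_subset[i]
        rows.append({"regulator": "REG_ACT", "target": e.gene,
                     "sign": int(np.sign(e.lfc))})
    for s in range(n_scrambled):
        picks = rng.choice(len(de_in_subset), size=n_targets, replace=False)
        flip = np.zeros(n_targets, dtype=bool)
        flip[rng.choice(n_targets, size=n_targets // 2, replace=False)] = True
        for i, fl in zip(picks, flip):
            e = de_in_subset[i]
            sign = int(np.sign(e.lfc)) * (-1 if fl else 1)
            rows.append({"regulator": f"REG_SCRAMBLED{s}",
                         "target": e.gene, "sign": sign})
    non_de = [g for g in truth.genes if g not in truth.de_genes()]
    for b in range(n_background):
        targets = rng.choice(non_de, size=background_targets, replace=False)
        for t in targets:
            rows.append({"regulator": f"REG_BG{b}", "target": str(t),
                         "sign": int(rng.choice([-1, 1]))})
    return pd.DataFrame(rows, columns=["regulator", "target", "sign"])


# ---------------------------------------------------------------------------
# stand-alone synergy benchmark generator

def simulate_synergy_dataset(n_samples: int = 80, n_decoys: int = 50,
                             coeff: float = 3.0, seed: int = 0
                             ) -> tuple[pd.DataFrame, np.ndarray,
                                        tuple[str, str]]:
    """Generate the two-gene synergy benchmark.

    Latent standardized expressions z_a, z_b and ``n_decoys`` decoy genes
    are iid N(0,1); the binary flight label is Bernoulli(σ(coeff·z_a·z_b)),
    so neither synergy gene is marginally predictive. Returns the
    gene×sample expression matrix, the labels, and the planted pair names.
    """
    rng = np.random.default_rng([int(seed), 13])
    while True:
        X = rng.standard_normal((2 + n_decoys, n_samples))
        y = (rng.random(n_samples) < _sigmoid(coeff * X[0] * X[1])).astype(int)
        if 4 <= y.sum() <= n_samples - 4:
            break
    names = ["SYN_A", "SYN_B"] + [f"NOISE{i:04d}" for i in range(n_decoys)]
    df = pd.DataFrame(X, index=pd.Index(names, name="gene_id"),
                      columns=[f"s{j}" for j in range(n_samples)])
    return df, y, ("SYN_A", "SYN_B")
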