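"""Synthetic study generator with known ground truth.

Emulates the study design end to end: three age groups (young reference
plus two aged groups), a latent per-animal physical-function value that
declines with age, five positive functional-test determinants that are
monotone in that latent value, an NB count matrix whose differentially
expressed fraction is much larger in the oldest group, and a subset of DE
genes whose expression is linearly coupled (on the log2 scale) to the
latent function. Young-animal libraries are generated twice — once per
sequencing run — with independent counts, mirroring re-prepared
technical-replicate libraries.

All randomness flows from a single master seed; each generation stage
draws from its own fixed-offset substream so stages stay reproducible
independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cfab import DETERMINANTS, FunctionalRecord
from .errors import ConfigError, FtxError

AGE_GROUPS = ("6m", "24m", "28m")

# Determinant scales: value = base * growth**(latent + noise), so raw
# measurements stay strictly positive and increase with latent function.
# Rotarod/cling bases echo the magnitudes of the worked reference values.
_DET_BASE = {
    "rotarod_s": 123.9,
    "grip_force": 110.0,
    "inverted_cling_s": 10**1.8,
    "treadmill_speed": 22.0,
    "vwr": 4800.0,
}
_DET_LOG2_SLOPE = {
    "rotarod_s": 0.35,
    "grip_force": 0.25,
    "inverted_cling_s": 0.45,
    "treadmill_speed": 0.30,
    "vwr": 0.80,
}

_TA_BASE_MG = 52.0
_TA_LOG2_SLOPE = 0.10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study."""

    n_per_group: tuple[int, int, int] = (7, 7, 8)
    n_genes: int = 2000
    frac_de_24m: float = 0.01
    frac_de_28m: float = 0.08
    log2fc_mean: float = 1.5
    log2fc_sd: float = 0.5
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.0
    libsize_sigma: float = 0.15
    n_coupled: int = 60
    coupling_sd: float = 0.25
    coupling_strength: float = 0.8
    coupling_mode: str = "opposed"  # "opposed" (sign vs age effect) or "random"
    coupled_lfc_sign: int | None = None  # force coupled genes' age effect sign (+1/-1)
    function_decline: tuple[float, float, float] = (0.0, -1.0, -2.5)
    latent_sd: float = 0.5
    determinant_noise_sd: float = 0.3
    mean_count_log: float = np.log(80.0)
    mean_count_sigma: float = 1.2
    two_run: bool = True
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != 3 or any(int(n) < 2 for n in self.n_per_group):
            raise ConfigError(f"n_per_group must be three integers >= 2, got {self.n_per_group}")
        for name in ("frac_de_24m", "frac_de_28m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        n_de_28m = int(round(self.frac_de_28m * self.n_genes))
        if self.n_coupled > n_de_28m:
            raise ConfigError(
                f"n_coupled ({self.n_coupled}) exceeds DE genes at 28m ({n_de_28m})"
            )
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ConfigError("dispersion trend coefficients must be non-negative")
        if self.coupling_mode not in ("opposed", "random"):
            raise ConfigError(f"unknown coupling_mode {self.coupling_mode!r}")
        if self.coupled_lfc_sign not in (None, 1, -1):
            raise ConfigError(f"coupled_lfc_sign must be None, 1 or -1, got {self.coupled_lfc_sign}")
        if self.libsize_sigma < 0 or self.latent_sd < 0 or self.determinant_noise_sd < 0:
            raise ConfigError("sigmas must be non-negative")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated study.

    genes: per-gene effective true log2fc per contrast plus coupling
        coefficient (0 when uncoupled). A gene is truly DE in a contrast
        iff its effective log2fc there is nonzero.
    latent: per-animal latent function value.
    size_factors: per-sample library-size factor.
    """

    genes: pd.DataFrame
    latent: pd.Series
    size_factors: pd.Series


@dataclass(frozen=True)
class FunctionData:
    records: list[FunctionalRecord]
    latent: pd.Series  # indexed by animal_id
    ta_mass_mg: pd.Series
    age_groups: pd.Series


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), offset])


def _animal_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, groups = [], []
    for prefix, group, n in zip("abc", AGE_GROUPS, config.n_per_group):
        for i in range(int(n)):
            ids.append(f"{prefix}{i + 1:02d}")
            groups.append(group)
    return ids, groups


def generate_function_data(config: SimulationConfig) -> FunctionData:
    """Latent function values, functional-test records and TA mass per animal."""
    config.validate()
    rng = _rng(config, 0)
    ids, groups = _animal_ids(config)
    shifts = dict(zip(AGE_GROUPS, config.function_decline))
    latent = np.array([shifts[g] for g in groups]) + rng.normal(0, config.latent_sd, len(ids))

    records = []
    for i, (animal, group) in enumerate(zip(ids, groups)):
        vals = {}
        for name in DETERMINANTS:
            noise = rng.normal(0, config.determinant_noise_sd)
            vals[name] = _DET_BASE[name] * 2.0 ** (_DET_LOG2_SLOPE[name] * (latent[i] + noise))
        records.append(FunctionalRecord(animal_id=animal, age_group=group, **vals))
    ta_noise = rng.normal(0, config.determinant_noise_sd, len(ids))
    ta = _TA_BASE_MG * 2.0 ** (_TA_LOG2_SLOPE * (latent + ta_noise))

    index = pd.Index(ids, name="animal_id")
    return FunctionData(
        records=records,
        latent=pd.Series(latent, index=index, name="latent_function"),
        ta_mass_mg=pd.Series(ta, index=index, name="ta_mass_mg"),
        age_groups=pd.Series(groups, index=index, name="age_group"),
    )


def _gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    gene_ids = [f"g{i + 1:06d}" for i in range(n)]
    q = rng.lognormal(config.mean_count_log, config.mean_count_sigma, n)

    design_lfc = {"24m": np.zeros(n), "28m": np.zeros(n)}
    n_de_24m = int(round(config.frac_de_24m * n))
    n_de_28m = int(round(config.frac_de_28m * n))
    de_28m = rng.choice(n, size=n_de_28m, replace=False)
    de_24m = rng.choice(n, size=n_de_24m, replace=False)
    for idx, key in ((de_24m, "24m"), (de_28m, "28m")):
        mag = np.abs(rng.normal(config.log2fc_mean, config.log2fc_sd, idx.size))
        signs = rng.permutation(np.where(np.arange(idx.size) < idx.size // 2, -1.0, 1.0))
        design_lfc[key][idx] = mag * signs

    coupling = np.zeros(n)
    coupled = rng.choice(de_28m, size=int(config.n_coupled), replace=False) if config.n_coupled else np.array([], dtype=int)
    if coupled.size:
        if config.coupled_lfc_sign is not None:
            design_lfc["28m"][coupled] = config.coupled_lfc_sign * np.abs(design_lfc["28m"][coupled])
        mag = np.abs(rng.normal(config.coupling_strength, 0.15, coupled.size))
        if config.coupling_mode == "opposed":
            signs = -np.sign(design_lfc["28m"][coupled])
        else:
            signs = rng.choice([-1.0, 1.0], coupled.size)
        coupling[coupled] = mag * signs

    return pd.DataFrame(
        {
            "q": q,
            "design_lfc_24m": design_lfc["24m"],
            "design_lfc_28m": design_lfc["28m"],
            "coupling": coupling,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def generate_counts(
    config: SimulationConfig, function_data: FunctionData
) -> tuple["pd.DataFrame", pd.DataFrame, SimulationTruth]:
    """NB count matrix, per-sample metadata, and the ground-truth tables.

    Counts are drawn per cell from NB(mean = sf * q * 2**x, variance =
    mu + alpha(mu) * mu^2) with alpha(mu) = a0 + a1/mu, where x combines
    the gene's group log2fc with, for coupled genes, coupling * latent
    (centered on the reference group) plus coupling noise. In two-run
    mode every reference animal contributes one independent library per
    run; aged animals appear in their own run only.
    """
    config.validate()
    latent = function_data.latent
    groups = function_data.age_groups
    missing = [a for a in groups.index if a not in latent.index]
    if missing:
        raise FtxError(f"latent function missing for animals {missing}")

    rng_genes = _rng(config, 1)
    rng_counts = _rng(config, 2)
    gene_truth = _gene_truth(config, rng_genes)

    samples: list[dict] = []
    for animal in groups.index:
        group = groups.loc[animal]
        if config.two_run:
            runs = (1, 2) if group == "6m" else ((1,) if group == "24m" else (2,))
        else:
            runs = (1,)
        for run in runs:
            samples.append(
                {"sample_id": f"{animal}_r{run}", "animal_id": animal, "age_group": group, "run": run}
            )
    meta = pd.DataFrame(samples).set_index("sample_id")

    n_samples = len(meta)
    sf = rng_counts.lognormal(0.0, config.libsize_sigma, n_samples)
    sf /= np.exp(np.log(sf).mean())  # geometric mean 1

    ref_shift = config.function_decline[0]
    latent_centered = (latent - ref_shift).loc[meta["animal_id"]].to_numpy()
    group_col = meta["age_group"].to_numpy()

    q = gene_truth["q"].to_numpy()[:, None]
    lfc = np.zeros((config.n_genes, n_samples))
    for key in ("24m", "28m"):
        mask = group_col == key
        lfc[:, mask] = gene_truth[f"design_lfc_{key}"].to_numpy()[:, None]
    coupling = gene_truth["coupling"].to_numpy()
    coupled_mask = coupling != 0
    x = lfc
    if coupled_mask.any():
        noise = rng_counts.normal(0, config.coupling_sd, (int(coupled_mask.sum()), n_samples))
        x[coupled_mask] += coupling[coupled_mask, None] * latent_centered[None, :] + noise

    mu = sf[None, :] * q * np.exp2(x)
    if not np.all(np.isfinite(mu)):
        raise FtxError("non-finite NB mean generated; check config magnitudes")
    alpha = config.dispersion_a0 + config.dispersion_a1 / mu
    counts = _nb_draw(rng_counts, mu, alpha)

    count_frame = pd.DataFrame(counts, index=gene_truth.index, columns=meta.index)

    # effective truth: the expected log2 group difference includes the
    # coupling contribution through the group shift in latent function
    eff = gene_truth[["coupling"]].copy()
    for i, key in enumerate(("24m", "28m"), start=1):
        shift = config.function_decline[i] - ref_shift
        eff[f"true_lfc_{key}"] = gene_truth[f"design_lfc_{key}"] + coupling * shift
        eff[f"is_de_{key}"] = eff[f"true_lfc_{key}"] != 0.0
    eff["baseline_mean"] = gene_truth["q"]

    # attach per-sample covariates: determinants + TA mass of the animal
    det = pd.DataFrame(
        {name: [getattr(r, name) for r in function_data.records] for name in DETERMINANTS},
        index=function_data.latent.index,
    )
    meta = meta.join(det, on="animal_id").join(function_data.ta_mass_mg, on="animal_id")

    truth = SimulationTruth(
        genes=eff,
        latent=latent.copy(),
        size_factors=pd.Series(sf, index=meta.index, name="size_factor"),
    )
    return count_frame, meta, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draws with mean mu and variance mu + alpha*mu^2 (Poisson when alpha=0)."""
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: function data + counts in one call."""
    fn = generate_function_data(config)
    counts, meta, truth = generate_counts(config, fn)
    return fn, counts, meta, truth


def simulate_gene_sets(
    truth: SimulationTruth,
    *,
    n_random_sets: int = 20,
    set_size: int = 40,
    seed: int = 0,
    loaded_term: str = "SET_COUPLED",
) -> dict[str, tuple[str, list[str]]]:
    """Gene-set collection with one term loaded with the coupled genes.

    Returns ``{term: (description, genes)}`` suitable for GMT writing:
    ``loaded_term`` holds every coupled gene (padded with random genes up
    to ``set_size``), plus ``n_random_sets`` random background terms.
    """
    rng = np.random.default_rng([int(seed), 17])
    all_genes = list(truth.genes.index)
    coupled = list(truth.genes.index[truth.genes["coupling"] != 0])
    sets: dict[str, tuple[str, list[str]]] = {}
    pad = max(0, set_size - len(coupled))
    pool = [g for g in all_genes if g not in set(coupled)]
    padding = list(rng.choice(pool, size=min(pad, len(pool)), replace=False)) if pad else []
    sets[loaded_term] = ("genes coupled to latent function", sorted(coupled) + sorted(padding))
    for i in range(n_random_sets):
        members = sorted(rng.choice(all_genes, size=min(set_size, len(all_genes)), replace=False))
        sets[f"SET_RAND{i + 1:03d}"] = ("random background term", list(members))
    return sets


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of the config with a different master seed."""
    return replace(config, seed=seed)
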