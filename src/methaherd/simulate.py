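"""Synthetic research-herd generator.

Generates a pedigree and longitudinal multi-trait weekly phenotypes with a
known additive-genetic / permanent-environment / residual decomposition, so
that every downstream stage (trait construction, relationship matrices,
REML, selection index) can be tested against known truth.

The generator simulates the repeatability animal model in the forward
direction for four base traits — energy-corrected milk (ECM, kg/d),
metabolic body weight (MBW, kg^0.75), dry matter intake (DMI, kg/d) and
methane production (MeP, g/d):

    y = mu + EYS + LACTWEEK + PAR + b*(age - mean age) + a + pe + e

with breeding values ``a`` drawn multivariate normal with covariance
``A (x) G`` over the pedigree, one permanent-environment draw per cow
(covariance PE) and an independent residual per cow-week (covariance E).

Raw measurement streams (milk/fat/protein, body weight, breath CH4/CO2
concentrations) are then *back-constructed* so that the trait-construction
pipeline recovers the simulated ECM, MBW, DMI and MeP values exactly: the
full pipeline, not just the arithmetic core, is testable.  Methane breath
concentration (MeC) is not independently controlled — it emerges from the
back-constructed CH4 ppm stream, as it would from a real sniffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, PedigreeError, relationship_matrix

BASE_TRAITS = ("ecm", "mbw", "dmi", "mep")

#: Milk composition used to back-construct milk/fat/protein from ECM:
#: fat and protein as mass fractions of milk volume.
FAT_FRACTION = 0.04
PROTEIN_FRACTION = 0.034
_ECM_PER_KG_MILK = 0.25 + 12.2 * FAT_FRACTION + 7.7 * PROTEIN_FRACTION

#: Baseline breath CO2 concentration (ppm) for back-constructed sniffer data.
CO2_BASELINE_PPM = 5000.0


class ConfigurationError(ValueError):
    """Raised for invalid simulation sizes or truth matrices."""


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int = 2,
    seed: int | None = None,
) -> Pedigree:
    """Random-mating pedigree in generation order.

    Founders (unknown parents) are split at random into sires and dams;
    within each later generation every dam is mated to one sire drawn
    uniformly at random (no selfing possible, no selection).  Each mating
    produces ``offspring_per_mating`` offspring, which form the next
    generation's parents.
    """
    if n_founders < 2:
        raise ConfigurationError("need at least 2 founders")
    if n_generations < 1:
        raise ConfigurationError("need at least 1 generation")
    if offspring_per_mating < 1:
        raise ConfigurationError("need at least 1 offspring per mating")
    rng = np.random.default_rng(seed)
    animal: list[int] = list(range(1, n_founders + 1))
    sire: list[int] = [0] * n_founders
    dam: list[int] = [0] * n_founders
    current = np.array(animal)
    next_id = n_founders + 1
    for _ in range(n_generations):
        perm = rng.permutation(current)
        n_sires = max(1, len(perm) // 2)
        sires, dams = perm[:n_sires], perm[n_sires:]
        if len(dams) == 0:
            sires, dams = perm[:1], perm[1:]
        offspring = []
        for d in dams:
            s = int(rng.choice(sires))
            for _ in range(offspring_per_mating):
                animal.append(next_id)
                sire.append(s)
                dam.append(int(d))
                offspring.append(next_id)
                next_id += 1
        current = np.array(offspring)
    return Pedigree(np.array(animal), np.array(sire), np.array(dam))


@dataclass
class FixedEffectSpec:
    """Levels and effect sizes of the model's fixed effects.

    The experiment-year-season (EYS) stratification uses 12 classes by
    default — enough strata to exercise the model while keeping every class
    well filled at a few hundred cows (a research-farm dataset spanning many
    years would have far more, which is configurable).  Lactation weeks 1-44
    follow a smooth lactation-curve shape scaled per trait; parities are
    1, 2 and 3+; age at calving enters as a linear covariate.
    """

    n_eys_classes: int = 12
    #: SD of the random EYS class effects, one per trait.
    eys_sd: tuple[float, ...] = (2.0, 3.0, 1.0, 20.0)
    #: Amplitude of the lactation-curve effect (SD units of the curve).
    lactation_amplitude: tuple[float, ...] = (3.0, 4.0, 1.5, 25.0)
    #: Additive effect of parity 1 / 2 / 3+, per trait.
    parity_effects: tuple[tuple[float, ...], ...] = (
        (0.0, 2.0, 3.0),
        (0.0, 4.0, 6.0),
        (0.0, 1.0, 1.5),
        (0.0, 15.0, 25.0),
    )
    #: Slope on (age at calving - 30) months, per trait.
    age_slope: tuple[float, ...] = (0.05, 0.2, 0.03, 0.5)

    def validate(self, n_traits: int) -> None:
        if self.n_eys_classes < 1:
            raise ConfigurationError("n_eys_classes must be >= 1")
        for name in ("eys_sd", "lactation_amplitude", "age_slope"):
            if len(getattr(self, name)) != n_traits:
                raise ConfigurationError(f"{name} must have one entry per trait")
        if len(self.parity_effects) != n_traits or any(
            len(p) != 3 for p in self.parity_effects
        ):
            raise ConfigurationError("parity_effects must be n_traits x 3")


def _check_psd(M: np.ndarray, name: str, k: int) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (k, k):
        raise ConfigurationError(f"{name} must be {k}x{k}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ConfigurationError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(M)) < -1e-8:
        raise ConfigurationError(f"{name} must be positive semidefinite")
    return M


@dataclass
class SimulationTruth:
    """True parameters of the simulated herd.

    ``G``, ``PE`` and ``E`` are the additive-genetic, permanent-environment
    and residual covariance matrices over ``trait_names`` (trait units
    squared); ``means`` are the trait means.  ``weeks_per_cow`` may be a
    single count or an inclusive ``(low, high)`` range sampled uniformly per
    cow (the distribution of records per cow is a free parameter).
    """

    trait_names: tuple[str, ...] = BASE_TRAITS
    means: tuple[float, ...] = (36.7, 121.2, 21.9, 337.9)
    G: np.ndarray = field(default=None)  # type: ignore[assignment]
    PE: np.ndarray = field(default=None)  # type: ignore[assignment]
    E: np.ndarray = field(default=None)  # type: ignore[assignment]
    fixed_effect_spec: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    n_cows: int = 600
    weeks_per_cow: int | tuple[int, int] = 30
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        if tuple(self.trait_names) != BASE_TRAITS:
            raise ConfigurationError(
                f"trait_names must be {BASE_TRAITS} (raw-stream back-construction "
                "is defined for these base traits)"
            )
        if self.G is None or self.PE is None or self.E is None:
            raise ConfigurationError("G, PE and E covariance matrices are required")
        self.G = _check_psd(self.G, "G", k)
        self.PE = _check_psd(self.PE, "PE", k)
        self.E = _check_psd(self.E, "E", k)
        if len(self.means) != k:
            raise ConfigurationError("means must have one entry per trait")
        lo, hi = self._weeks_range()
        if lo < 3:
            raise ConfigurationError("weeks_per_cow must be >= 3")
        if hi > 44:
            raise ConfigurationError("weeks_per_cow cannot exceed 44 lactation weeks")
        if self.n_cows < 1:
            raise ConfigurationError("n_cows must be >= 1")
        self.fixed_effect_spec.validate(k)

    def _weeks_range(self) -> tuple[int, int]:
        if isinstance(self.weeks_per_cow, (tuple, list)):
            lo, hi = self.weeks_per_cow
        else:
            lo = hi = int(self.weeks_per_cow)
        return int(lo), int(hi)

    def to_yaml(self, path) -> None:
        doc = {
            "trait_names": list(self.trait_names),
            "means": [float(m) for m in self.means],
            "G": np.asarray(self.G).tolist(),
            "PE": np.asarray(self.PE).tolist(),
            "E": np.asarray(self.E).tolist(),
            "fixed_effect_spec": asdict(self.fixed_effect_spec),
            "n_cows": int(self.n_cows),
            "weeks_per_cow": (
                list(self.weeks_per_cow)
                if isinstance(self.weeks_per_cow, (tuple, list))
                else int(self.weeks_per_cow)
            ),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationTruth":
        fes = doc.get("fixed_effect_spec", {})
        if isinstance(fes, dict):
            fes = {
                k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list)
                else v
                for k, v in fes.items()
            }
            fes = FixedEffectSpec(**fes)
        weeks = doc.get("weeks_per_cow", 30)
        if isinstance(weeks, list):
            weeks = tuple(weeks)
        return cls(
            trait_names=tuple(doc.get("trait_names", BASE_TRAITS)),
            means=tuple(doc.get("means", (36.7, 121.2, 21.9, 337.9))),
            G=np.asarray(doc["G"], dtype=float),
            PE=np.asarray(doc["PE"], dtype=float),
            E=np.asarray(doc["E"], dtype=float),
            fixed_effect_spec=fes,
            n_cows=int(doc.get("n_cows", 600)),
            weeks_per_cow=weeks,
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# Reference variance components for the four base traits, estimated in a
# ~650-cow Danish Holstein research herd with sniffer methane recording
# (diagonals of G/PE/E; MeP-ECM and MeP-MBW genetic correlations likewise
# from that source).  DMI components and the remaining correlations are not
# published for that herd and are plausible fill-ins, chosen once; they are
# demonstration values, not estimates.
_REF_VAR = {
    "ecm": (26.9, 9.1, 21.1),
    "mbw": (34.7, 26.1, 11.7),
    "dmi": (1.9, 1.6, 2.75),  # plausible: h2 ~ 0.30 at phenotypic SD 2.5
    "mep": (1160.6, 1456.8, 2923.9),
}
_REF_RG = np.array(
    [
        # ecm   mbw   dmi   mep
        [1.00, 0.10, 0.55, 0.79],
        [0.10, 1.00, 0.45, 0.32],
        [0.55, 0.45, 1.00, 0.60],
        [0.79, 0.32, 0.60, 1.00],
    ]
)
_REF_RPE = np.array(
    [
        [1.00, 0.20, 0.50, 0.50],
        [0.20, 1.00, 0.40, 0.20],
        [0.50, 0.40, 1.00, 0.50],
        [0.50, 0.20, 0.50, 1.00],
    ]
)
_REF_RE = np.array(
    [
        [1.00, 0.10, 0.30, 0.40],
        [0.10, 1.00, 0.20, 0.10],
        [0.30, 0.20, 1.00, 0.30],
        [0.40, 0.10, 0.30, 1.00],
    ]
)


def _cov_from_corr(corr: np.ndarray, variances: np.ndarray) -> np.ndarray:
    sd = np.sqrt(variances)
    return corr * np.outer(sd, sd)


def default_truth(
    n_cows: int = 600, weeks_per_cow: int | tuple[int, int] = 30, seed: int = 0
) -> SimulationTruth:
    """Study-condition truth: reference variance components and correlations."""
    var = np.array([_REF_VAR[t] for t in BASE_TRAITS])
    return SimulationTruth(
        G=_cov_from_corr(_REF_RG, var[:, 0]),
        PE=_cov_from_corr(_REF_RPE, var[:, 1]),
        E=_cov_from_corr(_REF_RE, var[:, 2]),
        n_cows=n_cows,
        weeks_per_cow=weeks_per_cow,
        seed=seed,
    )


def _chol_psd(M: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix (eigendecomposition fallback)."""
    M = np.asarray(M, dtype=float)
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _lactation_curve(weeks: np.ndarray) -> np.ndarray:
    """Smooth lactation-curve shape over weeks 1-44, centered, unit SD."""
    w = np.arange(1, 45, dtype=float)
    shape = w**0.2 * np.exp(-0.04 * w)
    shape = (shape - shape.mean()) / shape.std()
    return shape[weeks - 1]


@dataclass
class SimulatedHerd:
    """Output bundle of :func:`simulate_phenotypes`.

    ``records`` is the raw weekly-record table the trait pipeline consumes;
    ``latent`` holds the simulated (intended) trait values per cow-week;
    ``breeding_values`` the true additive values for every pedigree animal.
    """

    records: pd.DataFrame
    latent: pd.DataFrame
    breeding_values: pd.DataFrame
    truth: SimulationTruth
    n_clipped: int = 0


def simulate_phenotypes(
    pedigree: Pedigree,
    truth: SimulationTruth,
    seed: int | None = None,
) -> SimulatedHerd:
    """Simulate weekly records for the last ``truth.n_cows`` pedigree animals.

    A single master seed (``seed`` or ``truth.seed``) is split into
    deterministic per-component streams (breeding values, permanent
    environment, residuals, herd design).  Intended trait values are floored
    at a small positive value (counted in ``n_clipped``) so back-constructed
    raw streams stay physical; at the default parameters this is a < 1e-5
    tail event per record.
    """
    master = truth.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rng_bv, rng_pe, rng_e, rng_design, rng_fx = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    T = len(truth.trait_names)
    q = len(pedigree)
    if truth.n_cows > q:
        raise ConfigurationError("pedigree has fewer animals than n_cows")
    cows = pedigree.animal[-truth.n_cows :]

    # breeding values over the whole pedigree: vec covariance A (x) G
    A = relationship_matrix(pedigree).A
    L_A = _chol_psd(A)
    L_G = _chol_psd(truth.G)
    bv = L_A @ rng_bv.standard_normal((q, T)) @ L_G.T
    breeding_values = pd.DataFrame(bv, columns=list(truth.trait_names))
    breeding_values.insert(0, "animal", pedigree.animal)

    pe = rng_pe.standard_normal((truth.n_cows, T)) @ _chol_psd(truth.PE).T

    fes = truth.fixed_effect_spec
    eys_eff = rng_fx.normal(0.0, 1.0, size=(fes.n_eys_classes, T))
    eys_eff -= eys_eff.mean(axis=0, keepdims=True)
    eys_eff *= np.asarray(fes.eys_sd)
    par_eff = np.asarray(fes.parity_effects, dtype=float).T  # 3 x T -> (3, T)
    age_slope = np.asarray(fes.age_slope, dtype=float)
    lact_amp = np.asarray(fes.lactation_amplitude, dtype=float)

    lo, hi = truth._weeks_range()
    rows = []
    cow_bv = {int(a): bv[pedigree.index_of(int(a))] for a in cows}
    for c_ix, cow in enumerate(cows):
        n_weeks = int(rng_design.integers(lo, hi + 1))
        start_lw = int(rng_design.integers(1, 44 - n_weeks + 2))
        parity_ix = int(rng_design.choice(3, p=[0.5, 0.3, 0.2]))
        parity = ("1", "2", "3+")[parity_ix]
        age = float(
            (24.0, 36.0, 50.0)[parity_ix] + rng_design.uniform(0.0, 8.0)
        )
        eys_base = int(rng_design.integers(0, fes.n_eys_classes))
        resid = rng_e.standard_normal((n_weeks, T)) @ _chol_psd(truth.E).T
        for w in range(n_weeks):
            lw = start_lw + w
            eys = (eys_base + (lw // 11)) % fes.n_eys_classes
            y = (
                np.asarray(truth.means)
                + eys_eff[eys]
                + lact_amp * _lactation_curve(np.array([lw]))[0]
                + par_eff[parity_ix]
                + age_slope * (age - 30.0)
                + cow_bv[int(cow)]
                + pe[c_ix]
                + resid[w]
            )
            rows.append(
                (int(cow), w + 1, f"EYS{eys:02d}", lw, parity, age, *y)
            )
    latent = pd.DataFrame(
        rows,
        columns=[
            "cow_id",
            "week_index",
            "eys_class",
            "lactation_week",
            "parity",
            "age_at_calving_months",
            *truth.trait_names,
        ],
    )

    # floor intended traits at small positive values so raw streams are physical
    floor = 1e-6
    vals = latent[list(BASE_TRAITS)].to_numpy()
    n_clipped = int((vals < floor).sum())
    latent[list(BASE_TRAITS)] = np.maximum(vals, floor)

    records = _back_construct(latent)
    return SimulatedHerd(
        records=records,
        latent=latent,
        breeding_values=breeding_values,
        truth=truth,
        n_clipped=n_clipped,
    )


def _back_construct(latent: pd.DataFrame) -> pd.DataFrame:
    """Raw weekly streams whose trait pipeline reproduces the latent traits.

    Milk, fat and protein are set in fixed proportions yielding the intended
    ECM; body weight is ``MBW^(4/3)``; CO2 ppm is a fixed baseline and CH4
    ppm is set so that the HPU pipeline yields the intended MeP; pregnancy
    starts at lactation week 10.
    """
    out = latent[
        [
            "cow_id",
            "week_index",
            "eys_class",
            "lactation_week",
            "parity",
            "age_at_calving_months",
        ]
    ].copy()
    ecm = latent["ecm"].to_numpy()
    mbw = latent["mbw"].to_numpy()
    milk = ecm / _ECM_PER_KG_MILK
    out["milk_kg"] = milk
    out["fat_kg"] = FAT_FRACTION * milk
    out["protein_kg"] = PROTEIN_FRACTION * milk
    out["bw_kg"] = mbw ** (4.0 / 3.0)
    out["dmi_kg"] = latent["dmi"].to_numpy()
    days_pregnant = np.maximum(
        0, (latent["lactation_week"].to_numpy() - 10) * 7
    ).astype(float)
    out["days_pregnant"] = days_pregnant
    hpu = (5.6 * mbw + 22.0 * ecm + 1.6e-5 * days_pregnant**3) / 1000.0
    ratio = latent["mep"].to_numpy() / (180.0 * 24.0 * hpu * 0.668)
    out["co2_ppm"] = CO2_BASELINE_PPM
    out["ch4_ppm"] = ratio * CO2_BASELINE_PPM
    out["n_days_observed"] = 7
    return out
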