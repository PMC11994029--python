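"""Synthetic invasion-assay data: gLV batch dynamics plus plate-count noise.

The wet experiment this package analyses grows a five-species bacterial
community in closed batch culture for one week and reads out colony-forming
unit (CFU) densities by dilution plating.  This module stands in for that
experiment with the minimal mechanistic model expressing the community's
interaction structure, generalized Lotka-Volterra dynamics

    dN_i/dt = N_i * (r_i + sum_j alpha_ij * N_j),

where ``r_i`` is the intrinsic per-capita growth rate (per day) and
``alpha_ij`` the per-capita effect of species *j* on species *i*'s growth
(per CFU per day; ``alpha_ii`` < 0 is self-limitation).  A plate-count
observation layer adds Poisson colony-count noise and a detection limit, so
synthetic tables carry the same statistical structure (bounded growth,
count noise, censoring from rare populations) the downstream analysis must
survive.

Abundances are integrated in units of 1e6 CFU to keep the system
well-conditioned; the public interface is plain CFU throughout.

Three interaction presets are bundled:

``neutral``
    All species dynamically identical (equal ``r``, every ``alpha_ij``
    equal to ``alpha_ii``): no niche stabilization, every relative invader
    growth rate is exactly 1.  The null model for calibration checks.
``stabilized``
    Intraspecific limitation dominates (``|alpha_ii| > |alpha_ij|``):
    every rare invader grows faster per capita than the saturating
    residents, the signature of negative frequency dependence.
``paper_like``
    ``stabilized`` with one facilitation motif layered on: Variovorax (V)
    gains a growth benefit from Pseudomonas, Ochrobactrum and Achromobacter
    but not from Stenotrophomonas, matching the qualitative interaction
    network reported for this community.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .design import DEFAULT_POOL, SpeciesPool, TreatmentSpec

__all__ = [
    "CommunityParams",
    "InoculationScheme",
    "ObservationModel",
    "ConfigError",
    "InvalidTreatmentError",
    "DynamicsDivergenceError",
    "preset",
    "simulate_batch",
    "inoculate",
    "observe",
    "replicate_seed",
    "generate_dataset",
    "COUNTS_COLUMNS",
]

#: Internal abundance scale (CFU per model unit).
_SCALE = 1e6

#: Schema of the CFU counts table shared with the growth-statistics stage.
COUNTS_COLUMNS = (
    "treatment_id",
    "replicate",
    "species",
    "role",
    "N0",
    "N1",
    "below_detection",
    "assay_days",
)


class ConfigError(ValueError):
    """Invalid simulator or observation-model configuration."""


class InvalidTreatmentError(ValueError):
    """Treatment composition incompatible with the inoculation scheme."""


class DynamicsDivergenceError(RuntimeError):
    """gLV trajectory blew up (ill-posed interaction matrix)."""


@dataclass
class CommunityParams:
    """gLV parameterization of a species pool.

    Parameters
    ----------
    labels : tuple of str
        Species identifiers, fixing row/column order of ``alpha``.
    r : ndarray, shape (n,)
        Intrinsic growth rates, per day.
    alpha : ndarray, shape (n, n)
        Interaction matrix, per CFU per day; ``alpha[i, j]`` is the effect
        of species ``j`` on species ``i``.
    assay_days : float
        Batch duration, days (default 7: a one-week assay).
    """

    labels: tuple[str, ...]
    r: np.ndarray
    alpha: np.ndarray
    assay_days: float = 7.0

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        n = len(self.labels)
        self.r = np.asarray(self.r, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.r.shape != (n,):
            raise ConfigError(f"r must have shape ({n},), got {self.r.shape}")
        if self.alpha.shape != (n, n):
            raise ConfigError(
                f"alpha must be square of dimension {n}, got {self.alpha.shape}"
            )
        if not (np.isfinite(self.r).all() and np.isfinite(self.alpha).all()):
            raise ConfigError("non-finite entries in r or alpha")
        if self.assay_days <= 0:
            raise ConfigError("assay_days must be positive")

    @property
    def pool(self) -> SpeciesPool:
        return SpeciesPool(self.labels)


@dataclass
class InoculationScheme:
    """How treatment inocula are assembled.

    The resident community is inoculated at ``resident_total`` CFU split
    equally among residents; all invaders together receive
    ``invader_total`` CFU split equally, a 100-fold lower total at the
    defaults (16e6 vs 16e4 CFU).
    """

    resident_total: float = 16e6
    invader_total: float = 16e4
    within_group_ratios: str = "equal"

    def __post_init__(self) -> None:
        if self.resident_total <= 0 or self.invader_total <= 0:
            raise ConfigError("inoculum totals must be positive")
        if self.within_group_ratios != "equal":
            raise ConfigError(
                f"unsupported within_group_ratios {self.within_group_ratios!r}"
            )

    @property
    def fold_difference(self) -> float:
        return self.resident_total / self.invader_total


@dataclass
class ObservationModel:
    """Plate-count observation layer.

    ``effective_sampling_fraction`` is the fraction of culture CFUs
    represented by counted colonies (dilution times plated volume); with
    ``count_noise="poisson"`` the colony count is Poisson distributed and
    back-scaled, so observed counts have variance ``N / fraction``.  Counts
    below ``detection_limit`` (total-culture CFU equivalent; default 1e3,
    one colony at a typical plating dilution) are recorded as 0 with the
    below-detection flag set.
    """

    count_noise: str = "poisson"
    effective_sampling_fraction: float = 2e-5
    detection_limit: float = 1e3

    def __post_init__(self) -> None:
        if self.count_noise not in ("poisson", "none"):
            raise ConfigError(f"unknown count_noise {self.count_noise!r}")
        if not (0.0 < self.effective_sampling_fraction <= 1.0):
            raise ConfigError(
                "effective_sampling_fraction must be in (0, 1], got "
                f"{self.effective_sampling_fraction}"
            )
        if self.detection_limit < 0:
            raise ConfigError("detection_limit must be non-negative")


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

# Documented default magnitudes, in model units (rates per day; alpha per
# 1e6 CFU per day before rescaling to per-CFU).  Chosen so that communities
# inoculated at the default 16e6 + 16e4 CFU grow toward equilibria around
# 5e7-6e7 CFU total within the one-week assay, i.e. realistic 1/64-TSB
# batch yields, with no species starting above its equilibrium share.
_NEUTRAL_R = 1.0
_NEUTRAL_ALPHA = -0.02 / _SCALE  # shared by every entry: K_total = 5e7 CFU

_STABILIZED_R = (1.00, 1.05, 1.10, 1.15, 1.20)  # A, O, P, S, V
_STABILIZED_DIAG = -0.05 / _SCALE
_STABILIZED_OFFDIAG = -0.01 / _SCALE

_FACILITATION = 0.005 / _SCALE  # V's benefit from A, O, P in paper_like


def preset(name: str) -> CommunityParams:
    """Return one of the bundled five-species parameter sets."""
    labels = DEFAULT_POOL.labels
    n = len(labels)
    if name == "neutral":
        r = np.full(n, _NEUTRAL_R)
        alpha = np.full((n, n), _NEUTRAL_ALPHA)
    elif name in ("stabilized", "paper_like"):
        r = np.array(_STABILIZED_R)
        alpha = np.full((n, n), _STABILIZED_OFFDIAG)
        np.fill_diagonal(alpha, _STABILIZED_DIAG)
        if name == "paper_like":
            v = labels.index("V")
            for benefactor in ("A", "O", "P"):
                alpha[v, labels.index(benefactor)] = _FACILITATION
            alpha[v, labels.index("S")] = 0.0
    else:
        raise ConfigError(f"unknown preset {name!r}")
    return CommunityParams(labels=labels, r=r, alpha=alpha)


# --------------------------------------------------------------------------
# Dynamics
# --------------------------------------------------------------------------


def simulate_batch(params: CommunityParams, inoculum) -> np.ndarray:
    """Integrate the gLV batch from inoculation to the end of the assay.

    Parameters
    ----------
    inoculum : array-like, shape (n,)
        Per-species CFU at t=0, aligned with ``params.labels``.  Species at
        exactly 0 remain at 0.

    Returns
    -------
    ndarray of final per-species CFU counts (non-negative, deterministic).
    """
    x0 = np.asarray(inoculum, dtype=float) / _SCALE
    if x0.shape != (len(params.labels),):
        raise ConfigError(
            f"inoculum must have {len(params.labels)} entries, got {x0.shape}"
        )
    if (x0 < 0).any():
        raise ConfigError("negative inoculum")
    if not (x0 > 0).any():
        raise ConfigError("at least one species must be inoculated")

    r = params.r
    a = params.alpha * _SCALE  # per model-unit abundance

    def rhs(_t, x):
        return x * (r + a @ x)

    blowup = 1e9  # 1e15 CFU: far beyond any plausible batch yield

    def diverged(_t, x):
        return float(np.max(np.abs(x)) - blowup)

    diverged.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, params.assay_days),
        x0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-10,
        events=diverged,
    )
    bad = sol.status != 0 or not np.isfinite(sol.y[:, -1]).all()
    if bad:
        raise DynamicsDivergenceError(
            "gLV trajectory diverged or integration failed "
            f"(status={sol.status}); r={r.tolist()}, "
            f"alpha={params.alpha.tolist()}"
        )
    final = sol.y[:, -1]
    if final.min() < -1e-6:
        raise DynamicsDivergenceError(
            f"negative abundance {final.min()} in trajectory"
        )
    final = np.maximum(final, 0.0)
    final[x0 == 0] = 0.0
    return final * _SCALE


def inoculate(
    treatment: TreatmentSpec,
    scheme: InoculationScheme,
    labels=DEFAULT_POOL.labels,
) -> np.ndarray:
    """Per-species CFU inoculum for a treatment, aligned with ``labels``.

    Residents split ``resident_total`` equally; the focal plus co-invaders
    split ``invader_total`` equally; absent species get 0.
    """
    if not treatment.residents:
        raise InvalidTreatmentError(
            f"treatment {treatment.treatment_id} has no residents"
        )
    missing = treatment.species - set(labels)
    if missing:
        raise InvalidTreatmentError(
            f"treatment {treatment.treatment_id} uses species {sorted(missing)} "
            "absent from the community parameters"
        )
    per_resident = scheme.resident_total / len(treatment.residents)
    per_invader = scheme.invader_total / len(treatment.invaders)
    out = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab in treatment.residents:
            out[i] = per_resident
        elif lab in treatment.invaders:
            out[i] = per_invader
    return out


def observe(final, model: ObservationModel, rng_seed: int):
    """Apply the plate-count observation layer to true final densities.

    Returns ``(observed, below_detection)`` arrays; reproducible given the
    seed.
    """
    final = np.asarray(final, dtype=float)
    if (final < 0).any():
        raise ConfigError("negative final densities")
    if model.count_noise == "poisson":
        rng = np.random.default_rng(rng_seed)
        f = model.effective_sampling_fraction
        observed = rng.poisson(final * f).astype(float) / f
    else:
        observed = final.copy()
    below = observed < model.detection_limit
    observed = np.where(below, 0.0, observed)
    below = below | (observed == 0.0)
    return observed, below


def replicate_seed(master_seed: int, treatment_id: str, replicate: int) -> int:
    """Stable per-replicate seed: SeedSequence over the master seed, a
    CRC-32 of the treatment ID, and the replicate index.

    Independent of the order treatments are generated in, and stable
    across platforms and sessions (CRC-32 is a fixed function, unlike
    Python's salted ``hash``).
    """
    crc = zlib.crc32(treatment_id.encode("utf-8"))
    seq = np.random.SeedSequence([int(master_seed), crc, int(replicate)])
    return int(seq.generate_state(1, dtype=np.uint32)[0])


def generate_dataset(
    design: list[TreatmentSpec],
    params: CommunityParams,
    scheme: InoculationScheme | None = None,
    model: ObservationModel | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Simulate every treatment in a design and emit the CFU counts table.

    One row per treatment x replicate x inoculated species, in the schema
    :data:`COUNTS_COLUMNS`.  The deterministic dynamics are integrated once
    per treatment; observation noise is drawn per replicate with seeds from
    :func:`replicate_seed`, so the table is byte-identical for a given
    master seed regardless of generation order.
    """
    if not design:
        raise ConfigError("empty design")
    scheme = scheme or InoculationScheme()
    model = model or ObservationModel()
    labels = params.labels
    rows: list[tuple] = []
    for t in design:
        try:
            n0 = inoculate(t, scheme, labels)
            final = simulate_batch(params, n0)
        except (DynamicsDivergenceError, ConfigError, InvalidTreatmentError) as e:
            raise type(e)(f"treatment {t.treatment_id}: {e}") from e
        present = n0 > 0
        for rep in range(1, t.replicates + 1):
            seed = replicate_seed(master_seed, t.treatment_id, rep)
            obs, below = observe(final, model, seed)
            for i in np.flatnonzero(present):
                lab = labels[i]
                role = "invader" if lab in t.invaders else "resident"
                rows.append(
                    (
                        t.treatment_id,
                        rep,
                        lab,
                        role,
                        n0[i],
                        obs[i],
                        bool(below[i]),
                        params.assay_days,
                    )
                )
    return pd.DataFrame(rows, columns=list(COUNTS_COLUMNS))
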