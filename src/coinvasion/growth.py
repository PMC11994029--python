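"""Malthusian parameters and the relative invader growth rate (RGR).

The invasion criterion scores a focal species invading from rare by the
ratio of realized per-capita growth rates over the assay,

    m = ln(N1 / N0) / t,
    RGR = m_focal / m_community,

where ``m_community`` is the Malthusian parameter of *all other*
populations pooled by summed densities (residents and any co-invaders
together), not an average of per-species rates.  RGR > 1 means the rare
invader outgrew the established community — negative frequency dependence,
the signature of a stabilized, mutually invasible community.

Rates are reported per week (the assay's natural unit); RGR itself is
dimensionless and invariant to the time unit as long as both rates share
it.

Below-detection finals
----------------------
Plate counts censor rare populations: a focal species may finish below the
detection limit (recorded N1 = 0), where ``ln`` is undefined.  The paper
trail of such replicates is governed by an explicit
:class:`ImputationPolicy`:

* ``impute_at_limit`` (default) — set N1 to the detection limit, keeping
  the replicate with a strongly negative ``m_focal``; flagged ``imputed``.
* ``impute_half_limit`` — as above with half the limit.
* ``drop_replicate`` — record the estimate as undefined (NaN).

A community that declines overall (``m_community <= 0``) makes the ratio
uninterpretable as frequency dependence; such estimates are recorded as
undefined with the ``community_decline`` flag rather than as a signed
number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SpeciesPool, TreatmentSpec

__all__ = [
    "ImputationPolicy",
    "RgrEstimate",
    "InvalidInputError",
    "UndefinedCommunityError",
    "ReconciliationError",
    "malthusian",
    "pooled_malthusian",
    "relative_invader_growth_rate",
    "compute_all",
    "RGR_COLUMNS",
]

#: Days per week; rates are reported per week.
_WEEK = 7.0

RGR_COLUMNS = (
    "treatment_id",
    "replicate",
    "focal",
    "residents",
    "co_invaders",
    "invasion_type",
    "m_focal",
    "m_community",
    "rgr",
    "flags",
)


class InvalidInputError(ValueError):
    pass


class UndefinedCommunityError(ValueError):
    """Every non-focal population below detection: no community rate."""


class ReconciliationError(ValueError):
    """Counts table and design disagree (unknown treatments, missing
    species, missing replicates)."""


@dataclass(frozen=True)
class ImputationPolicy:
    """Policy for focal finals censored at the detection limit."""

    mode: str = "impute_at_limit"
    detection_limit: float = 1e3

    _MODES = ("impute_at_limit", "impute_half_limit", "drop_replicate")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise InvalidInputError(
                f"unknown imputation mode {self.mode!r}; choose from {self._MODES}"
            )
        if self.detection_limit <= 0:
            raise InvalidInputError("detection_limit must be positive")

    def imputed_final(self) -> float | None:
        """Replacement N1 for a censored focal final (None = drop)."""
        if self.mode == "impute_at_limit":
            return self.detection_limit
        if self.mode == "impute_half_limit":
            return self.detection_limit / 2.0
        return None


@dataclass
class RgrEstimate:
    """One focal invader's relative growth rate in one replicate."""

    treatment_id: str
    replicate: int
    focal: str
    m_focal: float
    m_community: float
    rgr: float
    flags: frozenset[str] = field(default_factory=frozenset)


def malthusian(N0: float, N1: float, t: float) -> float:
    """Realized per-capita growth rate ln(N1/N0)/t.

    ``t`` is in weeks; the result is per week.  Negative for decline.
    A zero N1 is a below-detection condition handled by the caller's
    imputation policy, not here.
    """
    if N0 <= 0:
        raise InvalidInputError(f"N0 must be positive, got {N0}")
    if t <= 0:
        raise InvalidInputError(f"assay time must be positive, got {t}")
    if N1 <= 0:
        raise InvalidInputError(
            f"N1 must be positive, got {N1} (below-detection values are "
            "resolved by the imputation policy before this point)"
        )
    return math.log(N1 / N0) / t


def pooled_malthusian(N0s, N1s, t: float) -> float:
    """Community Malthusian parameter from pooled densities.

    Pools by summed densities — ``ln(sum N1 / sum N0) / t`` — so the
    result is invariant to how populations are split into rows.  Members
    censored to zero at the final timepoint simply contribute zero to the
    pooled sum; only an entirely-censored community is undefined.
    """
    N0s = np.asarray(N0s, dtype=float)
    N1s = np.asarray(N1s, dtype=float)
    if N0s.size == 0:
        raise InvalidInputError("no community populations to pool")
    tot0, tot1 = N0s.sum(), N1s.sum()
    if tot1 <= 0:
        raise UndefinedCommunityError(
            "all community populations below detection at the final timepoint"
        )
    return malthusian(tot0, tot1, t)


def relative_invader_growth_rate(
    obs: pd.DataFrame,
    focal: str,
    policy: ImputationPolicy | None = None,
) -> RgrEstimate:
    """RGR of one focal invader from one replicate's observation rows.

    ``obs`` holds every inoculated population of a single treatment x
    replicate (columns ``species, role, N0, N1, assay_days`` at least).
    The focal row gives ``m_focal`` (imputation policy applied if censored);
    every other row — residents *and* co-invaders — is pooled for
    ``m_community``.
    """
    policy = policy or ImputationPolicy()
    is_focal = obs["species"] == focal
    if is_focal.sum() != 1:
        raise InvalidInputError(
            f"focal {focal!r} must appear exactly once, found {int(is_focal.sum())}"
        )
    frow = obs.loc[is_focal].iloc[0]
    if frow["role"] != "invader":
        raise InvalidInputError(f"focal {focal!r} is not an invader in this assay")
    others = obs.loc[~is_focal]
    if len(others) == 0:
        raise InvalidInputError("no community populations besides the focal")

    t_weeks = float(frow["assay_days"]) / _WEEK
    flags: set[str] = set()

    n1 = float(frow["N1"])
    if n1 <= 0:
        flags.add("focal_below_detection")
        replacement = policy.imputed_final()
        if replacement is None:
            m_focal = math.nan
        else:
            flags.add("imputed")
            m_focal = malthusian(float(frow["N0"]), replacement, t_weeks)
    else:
        m_focal = malthusian(float(frow["N0"]), n1, t_weeks)

    try:
        m_community = pooled_malthusian(
            others["N0"].to_numpy(), others["N1"].to_numpy(), t_weeks
        )
    except UndefinedCommunityError:
        m_community = math.nan
        flags.add("community_undefined")

    if math.isnan(m_focal) or math.isnan(m_community):
        rgr = math.nan
    elif m_community <= 0:
        rgr = math.nan
        flags.add("community_decline")
    else:
        rgr = m_focal / m_community

    return RgrEstimate(
        treatment_id=str(obs["treatment_id"].iloc[0]) if "treatment_id" in obs else "",
        replicate=int(obs["replicate"].iloc[0]) if "replicate" in obs else 0,
        focal=focal,
        m_focal=m_focal,
        m_community=m_community,
        rgr=rgr,
        flags=frozenset(flags),
    )


def compute_all(
    counts: pd.DataFrame,
    design: list[TreatmentSpec],
    pool: SpeciesPool,
    policy: ImputationPolicy | None = None,
) -> pd.DataFrame:
    """RGR estimates for every treatment x replicate of a design.

    Each design row names one focal invader, so a design of T treatments
    with R replicates yields T*R estimate rows (schema
    :data:`RGR_COLUMNS`; ``flags`` is a ``|``-joined string, empty when
    clean; undefined RGRs are NaN).  Counts and design are reconciled
    first: unknown treatment IDs, missing species or missing replicates
    raise :class:`ReconciliationError` listing every discrepancy.
    """
    policy = policy or ImputationPolicy()
    if counts.empty:
        raise ReconciliationError("empty counts table")
    missing_cols = {"treatment_id", "replicate", "species", "role", "N0", "N1", "assay_days"} - set(counts.columns)
    if missing_cols:
        raise ReconciliationError(f"counts table missing columns {sorted(missing_cols)}")

    by_tid = dict(tuple(counts.groupby("treatment_id", sort=False)))
    problems: list[str] = []
    for t in design:
        grp = by_tid.get(t.treatment_id)
        if grp is None:
            problems.append(f"no counts for treatment {t.treatment_id}")
            continue
        have = set(grp["species"])
        need = set(t.species)
        if need - have:
            problems.append(
                f"{t.treatment_id}: species {sorted(need - have)} missing from counts"
            )
        reps = set(grp["replicate"])
        if set(range(1, t.replicates + 1)) - reps:
            problems.append(f"{t.treatment_id}: missing replicates")
    unknown = set(by_tid) - {t.treatment_id for t in design}
    if unknown:
        problems.append(f"counts contain unknown treatments {sorted(unknown)}")
    if problems:
        raise ReconciliationError("; ".join(problems))

    rows = []
    for t in design:
        grp = by_tid[t.treatment_id]
        for rep, obs in grp.groupby("replicate", sort=True):
            est = relative_invader_growth_rate(obs, t.focal, policy)
            rows.append(
                (
                    t.treatment_id,
                    int(rep),
                    t.focal,
                    pool.join(t.residents),
                    pool.join(t.co_invaders),
                    t.invasion_type,
                    est.m_focal,
                    est.m_community,
                    est.rgr,
                    "|".join(sorted(est.flags)),
                )
            )
    return pd.DataFrame(rows, columns=list(RGR_COLUMNS))
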