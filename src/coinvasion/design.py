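"""Enumeration of single- and multi-species invasion assay designs.

An invasion assay introduces one or more species at low density (the
*invaders*) into an established *resident* community and asks whether each
invader can increase from rare.  Two families of design are supported:

* **single invasion** — one focal invader into a resident subset of the
  species pool (resident richness varied);
* **co-invasion** — an invader subset of size 2..(n-1) invades the
  complementary resident subset, so total richness is pinned at the pool
  size; every member of the invader subset serves in turn as the focal
  species whose relative growth rate is scored.

Treatments are identified deterministically from their composition, e.g.
``V_into_AP_with_OS`` (focal V invading residents {A, P} alongside
co-invaders {O, S}).  Ordering of species within IDs and of treatments in
enumerations follows the pool's label order, so two calls with the same
arguments produce byte-identical tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SpeciesPool",
    "TreatmentSpec",
    "PairingResult",
    "InvalidDesignError",
    "AmbiguousDesignError",
    "enumerate_co_invasion",
    "enumerate_single_invasion",
    "pair_by_residents",
    "design_to_frame",
    "write_design",
    "read_design",
    "DEFAULT_POOL",
]


class InvalidDesignError(ValueError):
    """Richness bounds or treatment composition violate the design rules."""


class AmbiguousDesignError(ValueError):
    """Two treatments in one list share the same (focal, residents) key."""


@dataclass(frozen=True)
class SpeciesPool:
    """Ordered set of community members.

    The label order is canonical: it defines the sort order used inside
    treatment IDs and the enumeration order of designs.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise InvalidDesignError("species pool needs at least 2 members")
        if len(set(labels)) != len(labels):
            raise InvalidDesignError(f"duplicate species labels: {labels}")
        if any(not lab for lab in labels):
            raise InvalidDesignError("empty species label")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def sort(self, species) -> tuple[str, ...]:
        """Sort species labels into canonical (pool) order."""
        order = {lab: i for i, lab in enumerate(self.labels)}
        unknown = [s for s in species if s not in order]
        if unknown:
            raise InvalidDesignError(f"species not in pool: {unknown}")
        return tuple(sorted(species, key=order.__getitem__))

    def join(self, species) -> str:
        """Serialize a species set as concatenated sorted labels.

        Single-character labels concatenate directly (``AP``); longer
        labels are joined with ``+`` so they can be split back.
        """
        ordered = self.sort(species)
        sep = "" if all(len(s) == 1 for s in self.labels) else "+"
        return sep.join(ordered)

    def split(self, text: str) -> tuple[str, ...]:
        """Inverse of :meth:`join`."""
        if not text:
            return ()
        if all(len(s) == 1 for s in self.labels):
            return tuple(text)
        return tuple(text.split("+"))


#: The five-member soil bacterial community the default analyses target:
#: Achromobacter (A), Ochrobactrum (O), Pseudomonas (P),
#: Stenotrophomonas (S), Variovorax (V).
DEFAULT_POOL = SpeciesPool(("A", "O", "P", "S", "V"))


@dataclass(frozen=True)
class TreatmentSpec:
    """One invasion assay: a focal invader, its resident community, and any
    co-invaders introduced alongside it."""

    treatment_id: str
    focal: str
    residents: frozenset[str]
    co_invaders: frozenset[str]
    invasion_type: str  # "single" | "co"
    replicates: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "residents", frozenset(self.residents))
        object.__setattr__(self, "co_invaders", frozenset(self.co_invaders))
        if self.focal in self.residents or self.focal in self.co_invaders:
            raise InvalidDesignError(
                f"focal {self.focal!r} overlaps residents/co-invaders"
            )
        if self.residents & self.co_invaders:
            raise InvalidDesignError("residents and co-invaders overlap")
        if self.invasion_type not in ("single", "co"):
            raise InvalidDesignError(f"bad invasion_type {self.invasion_type!r}")
        if (self.invasion_type == "single") != (len(self.co_invaders) == 0):
            raise InvalidDesignError(
                "invasion_type 'single' iff there are no co-invaders"
            )
        if self.replicates < 1:
            raise InvalidDesignError("replicates must be positive")

    @property
    def invaders(self) -> frozenset[str]:
        """All rare species: the focal plus its co-invaders."""
        return self.co_invaders | {self.focal}

    @property
    def species(self) -> frozenset[str]:
        return self.residents | self.invaders


def _treatment_id(pool: SpeciesPool, focal: str, residents, co_invaders) -> str:
    tid = f"{focal}_into_{pool.join(residents)}"
    if co_invaders:
        tid += f"_with_{pool.join(co_invaders)}"
    return tid


def make_treatment(
    pool: SpeciesPool,
    focal: str,
    residents,
    co_invaders=(),
    replicates: int = 6,
) -> TreatmentSpec:
    """Build a :class:`TreatmentSpec` with its canonical deterministic ID."""
    residents = frozenset(residents)
    co_invaders = frozenset(co_invaders)
    for s in {focal} | residents | co_invaders:
        if s not in pool.labels:
            raise InvalidDesignError(f"species {s!r} not in pool {pool.labels}")
    return TreatmentSpec(
        treatment_id=_treatment_id(pool, focal, residents, co_invaders),
        focal=focal,
        residents=residents,
        co_invaders=co_invaders,
        invasion_type="co" if co_invaders else "single",
        replicates=replicates,
    )


def _check_richness(lo: int, hi: int, n: int, what: str) -> None:
    if not (1 <= lo <= hi <= n - 1):
        raise InvalidDesignError(
            f"{what} richness bounds [{lo}, {hi}] outside [1, {n - 1}] "
            f"for a pool of {n}"
        )


def enumerate_co_invasion(
    pool: SpeciesPool,
    invader_richness_min: int = 2,
    invader_richness_max: int = 4,
    replicates: int = 6,
) -> list[TreatmentSpec]:
    """Enumerate the co-invasion design over a species pool.

    Total richness is held at the pool size: every invader subset *I* with
    ``|I|`` in the requested range invades the complementary resident set
    ``pool \\ I``, and each member of *I* in turn is the focal species.
    For the default five-species pool with invader richness 2–4 this gives
    sum(k*C(5,k)) = 70 treatments, 14 per focal species.
    """
    n = len(pool)
    _check_richness(invader_richness_min, invader_richness_max, n, "invader")
    out: list[TreatmentSpec] = []
    for k in range(invader_richness_min, invader_richness_max + 1):
        for invaders in itertools.combinations(pool.labels, k):
            residents = frozenset(pool.labels) - frozenset(invaders)
            for focal in invaders:  # pool order within the subset
                out.append(
                    make_treatment(
                        pool,
                        focal,
                        residents,
                        frozenset(invaders) - {focal},
                        replicates,
                    )
                )
    return out


def enumerate_single_invasion(
    pool: SpeciesPool,
    resident_richness_min: int = 1,
    resident_richness_max: int | None = None,
    replicates: int = 6,
) -> list[TreatmentSpec]:
    """Enumerate single-focal invasions over all resident subsets.

    Every species invades every subset of the others whose size lies in the
    requested resident-richness range; count = n * sum_k C(n-1, k).  The
    full range 1..(n-1) over five species yields 75 treatments.
    """
    n = len(pool)
    if resident_richness_max is None:
        resident_richness_max = n - 1
    _check_richness(resident_richness_min, resident_richness_max, n, "resident")
    out: list[TreatmentSpec] = []
    for focal in pool.labels:
        others = [s for s in pool.labels if s != focal]
        for k in range(resident_richness_min, resident_richness_max + 1):
            for residents in itertools.combinations(others, k):
                out.append(make_treatment(pool, focal, residents, (), replicates))
    return out


@dataclass
class PairingResult:
    """Co-invasion treatments matched to the single-invasion assays that
    share the same focal species and resident community."""

    pairs: list[tuple[TreatmentSpec, TreatmentSpec]] = field(default_factory=list)
    unpaired_co: list[TreatmentSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def _key_index(treatments, what: str):
    index: dict[tuple[str, frozenset[str]], TreatmentSpec] = {}
    for t in treatments:
        key = (t.focal, t.residents)
        if key in index:
            raise AmbiguousDesignError(
                f"duplicate (focal, residents) in {what} list: "
                f"{t.treatment_id} vs {index[key].treatment_id}"
            )
        index[key] = t
    return index


def pair_by_residents(co, single) -> PairingResult:
    """Match each co-invasion treatment to the single-invasion treatment
    with the same focal species and the same resident set.

    Co-invasion treatments without a counterpart are reported unpaired;
    duplicated (focal, residents) keys in either list raise
    :class:`AmbiguousDesignError`.
    """
    _key_index(co, "co")  # duplicate check only
    singles = _key_index(single, "single")
    result = PairingResult()
    for t in co:
        match = singles.get((t.focal, t.residents))
        if match is None:
            result.unpaired_co.append(t)
        else:
            result.pairs.append((t, match))
    return result


def design_to_frame(treatments, pool: SpeciesPool) -> pd.DataFrame:
    """Serialize a treatment list as the canonical design table."""
    return pd.DataFrame(
        {
            "treatment_id": [t.treatment_id for t in treatments],
            "focal": [t.focal for t in treatments],
            "residents": [pool.join(t.residents) for t in treatments],
            "co_invaders": [pool.join(t.co_invaders) for t in treatments],
            "invasion_type": [t.invasion_type for t in treatments],
            "replicates": [t.replicates for t in treatments],
        }
    )


def write_design(treatments, pool: SpeciesPool, path) -> None:
    design_to_frame(treatments, pool).to_csv(path, index=False)


def read_design(path, pool: SpeciesPool) -> list[TreatmentSpec]:
    """Read a design table back into :class:`TreatmentSpec` objects."""
    df = pd.read_csv(path, dtype={"residents": str, "co_invaders": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            make_treatment(
                pool,
                row.focal,
                pool.split(row.residents),
                pool.split(row.co_invaders),
                int(row.replicates),
            )
        )
    return out
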