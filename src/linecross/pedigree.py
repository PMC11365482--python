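"""Cohort pedigrees and composite-genetic-effect coefficients (the c-matrix).

A line cross design starts from two founder strains (P1, P2) and derives
cohorts by crossing: an F1 hybrid, an F2 (selfed F1), backcrosses to either
parent, and so on.  Each cohort has a definite *expected* exposure to each
composite genetic effect — autosomal additive (Aa), autosomal dominance
(Ad), cytotype additive (Ca), maternal-effect additive/dominance (Mea/Med)
and the two-way epistatic combinations of Aa, Ad and Ca.  The table of these
exposures across cohorts is the c-matrix: the design matrix of line cross
analysis.

Coefficients use the parental ±1 scale: the P1 founder has Aa = +1, the P2
founder Aa = −1, and a 50/50 hybrid Aa = 0.

The recursion implemented here assumes independent gamete draws from each
parent's genome composition, which is exact for crosses among the founders,
their F1, and any combination of those (F2, backcrosses, reciprocals).  It
is not valid for designs with linkage or selection within cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "EFFECT_LABELS",
    "BASE_EFFECTS",
    "EPISTATIC_EFFECTS",
    "CohortPedigree",
    "BaseCoefficients",
    "PedigreeError",
    "founder",
    "cross",
    "derive_base_coefficients",
    "derive_composite_coefficients",
    "build_cmatrix",
    "study_pedigree",
    "load_pedigree",
    "write_cmatrix",
    "read_cmatrix",
]

BASE_EFFECTS = ("Aa", "Ad", "Ca", "Mea", "Med")

#: two-way epistatic effects and their constituent base effects
EPISTATIC_EFFECTS: Mapping[str, tuple[str, str]] = {
    "AaAa": ("Aa", "Aa"),
    "AaAd": ("Aa", "Ad"),
    "AdAd": ("Ad", "Ad"),
    "AaCa": ("Aa", "Ca"),
    "AdCa": ("Ad", "Ca"),
}

#: the ten composite genetic effects estimable from a two-founder cross design
EFFECT_LABELS = BASE_EFFECTS + tuple(EPISTATIC_EFFECTS)


class PedigreeError(ValueError):
    """Raised for unresolvable, cyclic, or otherwise invalid pedigrees."""


@dataclass(frozen=True)
class CohortPedigree:
    """A cohort defined by its sire and dam (or as a founder strain).

    Founders are terminal nodes carrying ``founder_role`` "P1" or "P2";
    derived cohorts reference two parent pedigrees.  Selfed cohorts are
    represented by ``sire is dam``.
    """

    name: str
    sire: "CohortPedigree | None" = None
    dam: "CohortPedigree | None" = None
    founder_role: str | None = None

    def __post_init__(self) -> None:
        if self.founder_role is not None:
            if self.founder_role not in ("P1", "P2"):
                raise PedigreeError(
                    f"founder_role must be 'P1' or 'P2', got {self.founder_role!r}"
                )
        elif self.sire is None or self.dam is None:
            raise PedigreeError(
                f"cohort {self.name!r} needs either a founder role or both parents"
            )

    @property
    def is_founder(self) -> bool:
        return self.founder_role is not None

    def __repr__(self) -> str:  # compact; full tree reprs explode
        if self.is_founder:
            return f"CohortPedigree({self.name!r}, founder={self.founder_role})"
        return f"CohortPedigree({self.name!r}, {self.sire.name} x {self.dam.name})"


def founder(name: str, role: str) -> CohortPedigree:
    """A founder strain cohort (maintained by selfing); ``role`` is 'P1' or 'P2'."""
    return CohortPedigree(name=name, founder_role=role)


def cross(name: str, sire: CohortPedigree, dam: CohortPedigree) -> CohortPedigree:
    """The cohort produced by crossing ``sire`` × ``dam`` (sire-by-dam order)."""
    return CohortPedigree(name=name, sire=sire, dam=dam)


@dataclass(frozen=True)
class BaseCoefficients:
    """The five base composite-effect coefficients of one cohort.

    Aa is 2θ − 1 where θ is the expected P1 genome proportion; Ad is the
    expected heterozygosity (probability a random locus carries one allele
    from each founder); Ca is the cytotype sign (+1 when the strict maternal
    lineage ends at P1); Mea and Med are the dam's Aa and Ad.
    """

    Aa: float
    Ad: float
    Ca: float
    Mea: float
    Med: float

    def as_dict(self) -> dict[str, float]:
        return {e: getattr(self, e) for e in BASE_EFFECTS}


def _theta(p: CohortPedigree, _stack: frozenset[int] = frozenset()) -> float:
    """Expected proportion of the genome inherited from the P1 founder."""
    if id(p) in _stack:
        raise PedigreeError(f"cycle in ancestry of cohort {p.name!r}")
    if p.is_founder:
        return 1.0 if p.founder_role == "P1" else 0.0
    s = _stack | {id(p)}
    return 0.5 * (_theta(p.sire, s) + _theta(p.dam, s))


def _heterozygosity(p: CohortPedigree) -> float:
    # independent-gamete assumption: each parent transmits a P1 allele with
    # probability equal to its own genome-wide theta
    if p.is_founder:
        return 0.0
    ts, td = _theta(p.sire), _theta(p.dam)
    return ts * (1.0 - td) + td * (1.0 - ts)


def _cytotype(p: CohortPedigree, _stack: frozenset[int] = frozenset()) -> float:
    if id(p) in _stack:
        raise PedigreeError(f"cycle in maternal lineage of cohort {p.name!r}")
    if p.is_founder:
        return 1.0 if p.founder_role == "P1" else -1.0
    return _cytotype(p.dam, _stack | {id(p)})


def derive_base_coefficients(pedigree: CohortPedigree) -> BaseCoefficients:
    """Derive Aa, Ad, Ca, Mea, Med for one cohort from its pedigree.

    The recursion: θ(P1 founder) = 1, θ(P2 founder) = 0, θ(child) is the
    parents' mean; Aa = 2θ − 1.  Ad of a founder is 0 and of a child is
    θ_s(1−θ_d) + θ_d(1−θ_s).  Ca follows the dam lineage down to a founder.
    Maternal coefficients are the dam's own Aa and Ad; a founder (selfed)
    is its own dam.
    """
    theta = _theta(pedigree)
    aa = 2.0 * theta - 1.0
    ad = _heterozygosity(pedigree)
    ca = _cytotype(pedigree)
    dam = pedigree if pedigree.is_founder else pedigree.dam
    mea = 2.0 * _theta(dam) - 1.0
    med = _heterozygosity(dam)
    return BaseCoefficients(Aa=aa, Ad=ad, Ca=ca, Mea=mea, Med=med)


def derive_composite_coefficients(base: BaseCoefficients, effect: str) -> float:
    """Coefficient of any of the ten supported composite effects.

    Base effects are returned directly; a two-way epistatic coefficient is
    the product of its two constituent base coefficients.
    """
    if effect in BASE_EFFECTS:
        return getattr(base, effect)
    if effect in EPISTATIC_EFFECTS:
        a, b = EPISTATIC_EFFECTS[effect]
        return getattr(base, a) * getattr(base, b) + 0.0  # +0.0 folds -0.0 into 0.0
    raise ValueError(
        f"unknown effect label {effect!r}; supported labels: {', '.join(EFFECT_LABELS)}"
    )


def build_cmatrix(
    cohorts: Sequence[CohortPedigree],
    effects: Iterable[str] = EFFECT_LABELS,
) -> pd.DataFrame:
    """Build the cohorts × effects coefficient table (c-matrix).

    Returns a DataFrame indexed by cohort name (input order preserved) with
    one column per requested effect label.
    """
    effects = tuple(effects)
    if len(cohorts) < 2:
        raise PedigreeError("a c-matrix needs at least two cohorts")
    if not effects:
        raise ValueError("effects must be non-empty")
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PedigreeError(f"duplicate cohort names: {', '.join(dupes)}")
    rows = []
    for c in cohorts:
        base = derive_base_coefficients(c)
        rows.append({e: derive_composite_coefficients(base, e) for e in effects})
    cm = pd.DataFrame(rows, index=pd.Index(names, name="cohort"), columns=list(effects))
    return cm


def study_pedigree() -> dict[str, CohortPedigree]:
    """The five-cohort interspecific tomato design: P1, P2, F2, BC1, rBC2.

    P1 is the wild desert parent, P2 the domesticated parent; the F1
    (P1 × P2) is used only as a parent of the derived cohorts and is not
    itself part of the measured set.
    """
    p1 = founder("P1", "P1")
    p2 = founder("P2", "P2")
    f1 = cross("F1", p1, p2)
    return {
        "P1": p1,
        "P2": p2,
        "F2": cross("F2", f1, f1),
        "BC1": cross("BC1", p1, f1),
        "rBC2": cross("rBC2", f1, p2),
    }


def load_pedigree(path: str | Path) -> dict[str, CohortPedigree]:
    """Read a pedigree configuration (YAML mapping of cohort definitions).

    Each cohort is either ``{founder: P1}`` / ``{founder: P2}`` or
    ``{sire: <name>, dam: <name>}`` referencing earlier-defined cohorts.
    Returns cohorts in file order.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "cohorts" not in raw:
        raise PedigreeError(f"{path}: expected a top-level 'cohorts' mapping")
    built: dict[str, CohortPedigree] = {}
    for name, entry in raw["cohorts"].items():
        if not isinstance(entry, dict):
            raise PedigreeError(f"{path}: cohort {name!r} must map to a dict")
        if "founder" in entry:
            built[name] = founder(str(name), str(entry["founder"]))
            continue
        try:
            sire_name, dam_name = entry["sire"], entry["dam"]
        except KeyError as exc:
            raise PedigreeError(
                f"{path}: cohort {name!r} needs 'founder' or both 'sire' and 'dam'"
            ) from exc
        for parent in (sire_name, dam_name):
            if parent not in built:
                raise PedigreeError(
                    f"{path}: cohort {name!r} references undefined parent {parent!r} "
                    "(parents must be defined before their offspring)"
                )
        built[name] = cross(str(name), built[sire_name], built[dam_name])
    return built


def write_cmatrix(cmatrix: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a c-matrix as delimited text (cohort label column + effect header)."""
    cmatrix.to_csv(path, sep=sep)


def read_cmatrix(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a c-matrix written by :func:`write_cmatrix`."""
    return pd.read_csv(path, sep=sep, index_col=0)
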