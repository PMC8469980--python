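"""Synthetic dual-scale cohorts via a single-latent-factor Gaussian copula.

Real validation data for frailty screening scales are rarely shareable, so
the package ships a generator that emulates the published validation cohort:
each patient carries a standard-normal latent frailty ``f``; every
questionnaire item observes a noisy projection of it and is thresholded to
its binary (ZFS) or three-level ordinal (mSEGA) coding at cut-offs calibrated
so the marginal prevalences hit their published targets exactly in
expectation.  Near-duplicate item pairs across the two scales ("twins", e.g.
self-reported memory complaint vs the mSEGA cognition item) additionally
share a residual, reproducing the strong off-diagonal entries of the
published cross-scale correlation matrix without attempting to match a full
19x19 correlation target, which the printed summaries cannot identify.

Item latent (unit variance by construction):

    y_item = lambda * f + rho * g_pair + sqrt(1 - lambda^2 - rho^2) * eps

with ``g_pair`` shared by the two members of a twin pair (rho = 0 otherwise).
A binary item fires iff y > Phi^{-1}(1 - p); ordinal items use two such
thresholds.  Each column draws from its own seeded stream, so adding an item
to a spec never perturbs previously generated columns under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .scales import MSEGA_ITEMS, ZFS_ITEMS

__all__ = [
    "ItemSpec",
    "TwinPair",
    "SimSpec",
    "calibrate_threshold",
    "generate_cohort",
    "default_spec",
    "load_spec_config",
]


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item of the generative model.

    ``marginal`` is the target prevalence p for a binary item, or the
    category probabilities (p0, p1, p2) for an ordinal item.  ``loading`` is
    the item's coefficient on the shared latent frailty factor.
    """

    name: str
    scale: str  # "zfs" | "msega"
    kind: str   # "binary" | "ordinal3"
    marginal: float | tuple[float, float, float]
    loading: float

    def validate(self) -> None:
        if self.scale not in ("zfs", "msega"):
            raise ValueError(f"{self.name}: scale must be 'zfs' or 'msega'")
        if self.kind == "binary":
            p = self.marginal
            if not isinstance(p, (int, float)) or not 0 < p < 1:
                raise ValueError(f"{self.name}: binary marginal must be in (0, 1), got {p!r}")
        elif self.kind == "ordinal3":
            probs = self.marginal
            if (
                not isinstance(probs, tuple)
                or len(probs) != 3
                or any(not 0 < q < 1 for q in probs)
            ):
                raise ValueError(f"{self.name}: ordinal marginal must be 3 probabilities in (0,1)")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: ordinal probabilities must sum to 1, got {probs}")
        else:
            raise ValueError(f"{self.name}: kind must be 'binary' or 'ordinal3'")
        if not 0 <= self.loading < 1:
            raise ValueError(f"{self.name}: loading must be in [0, 1), got {self.loading}")


@dataclass(frozen=True)
class TwinPair:
    """A near-duplicate item pair sharing a residual with coupling rho."""

    zfs_item: str
    msega_item: str
    rho: float


@dataclass(frozen=True)
class SimSpec:
    """Full specification of a synthetic cohort (deterministic given ``seed``)."""

    n: int
    seed: int
    items: tuple[ItemSpec, ...]
    twin_pairs: tuple[TwinPair, ...] = ()
    demographics: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    age_loading: float = 0.35
    sex_female_p: float = 0.5

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate item names in spec")
        by_name = {it.name: it for it in self.items}
        for it in self.items:
            it.validate()
        paired: set[str] = set()
        for pair in self.twin_pairs:
            for member in (pair.zfs_item, pair.msega_item):
                if member not in by_name:
                    raise ValueError(f"twin pair references unknown item {member!r}")
                if member in paired:
                    raise ValueError(f"item {member!r} appears in more than one twin pair")
                paired.add(member)
                lam = by_name[member].loading
                if not 0 <= pair.rho < 1 or lam**2 + pair.rho**2 >= 1:
                    raise ValueError(
                        f"item {member!r}: loading^2 + rho^2 must be < 1 "
                        f"(lambda={lam}, rho={pair.rho})"
                    )
        for name, (mean, sd) in self.demographics.items():
            if sd < 0:
                raise ValueError(f"demographic {name!r}: sd must be >= 0")
        if not 0 <= self.age_loading < 1:
            raise ValueError(f"age_loading must be in [0, 1), got {self.age_loading}")
        if not 0 < self.sex_female_p < 1:
            raise ValueError("sex_female_p must be in (0, 1)")


def calibrate_threshold(p: float) -> float:
    """Standard-normal threshold tau with P(Z > tau) = p."""
    if not 0 < p < 1:
        raise ValueError(f"prevalence must be in (0, 1), got {p}")
    return float(stats.norm.isf(p))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _item_column(item: ItemSpec, latent: np.ndarray) -> np.ndarray:
    if item.kind == "binary":
        return (latent > calibrate_threshold(item.marginal)).astype(int)
    p0, p1, p2 = item.marginal
    tau1 = calibrate_threshold(p1 + p2)  # crossing into category >= 1
    tau2 = calibrate_threshold(p2)       # crossing into category 2
    return (latent > tau1).astype(int) + (latent > tau2).astype(int)


def generate_cohort(spec: SimSpec) -> pd.DataFrame:
    """Draw a synthetic cohort; identical specs produce identical tables.

    Stream layout (all derived from ``spec.seed``): the latent frailty factor,
    one shared-residual stream per twin pair (pair order), one residual stream
    per item (item order), then demographic streams — so cohorts are stable
    under appending items or demographics.
    """
    spec.validate()
    n = spec.n
    factor = _rng(spec.seed, 0).standard_normal(n)
    pair_residual: dict[str, np.ndarray] = {}
    pair_rho: dict[str, float] = {}
    for j, pair in enumerate(spec.twin_pairs):
        g = _rng(spec.seed, 1, j).standard_normal(n)
        for member in (pair.zfs_item, pair.msega_item):
            pair_residual[member] = g
            pair_rho[member] = pair.rho

    data: dict[str, object] = {"patient_id": [f"s{i:05d}" for i in range(n)]}
    for i, item in enumerate(spec.items):
        lam = item.loading
        rho = pair_rho.get(item.name, 0.0)
        eps = _rng(spec.seed, 2, i).standard_normal(n)
        latent = lam * factor + rho * pair_residual.get(item.name, 0.0) \
            + np.sqrt(1.0 - lam**2 - rho**2) * eps
        data[f"{item.scale}_{item.name}"] = _item_column(item, latent)

    for d, (name, (mean, sd)) in enumerate(sorted(spec.demographics.items())):
        eps = _rng(spec.seed, 3, d).standard_normal(n)
        if name == "age":
            # frailty rises with age: age shares the latent factor
            al = spec.age_loading
            draw = mean + sd * (al * factor + np.sqrt(1 - al**2) * eps)
            data[name] = np.round(draw).astype(int)
        else:
            data[name] = np.round(mean + sd * eps, 2)
    sex_u = _rng(spec.seed, 4).random(n)
    data["sex"] = np.where(sex_u < spec.sex_female_p, "F", "M")
    return pd.DataFrame(data)


# Default loadings: chosen once to reproduce, simultaneously, the published
# item prevalences (exact in expectation, by construction), an mSEGA-frailty
# prevalence near 19.6%, a cross-scale total-score correlation near 0.81, and
# twin-pair dominance within each row of the item correlation matrix.  The
# calibration run lives in scripts/calibrate_simulator.py.
_ZFS_MARGINALS = {name: count / reference.COHORT_N
                  for name, count in reference.item_prevalences().items()}

_ZFS_LOADINGS = {
    "weight_loss_ge5pct_6mo": 0.480,
    "monopodal_stance_lt5s": 0.864,
    "lives_alone": 0.600,
    "home_aid_present": 0.674,
    "memory_complaint": 0.696,
    "polypharmacy_ge5_classes": 0.713,
}

# Ordinal category probabilities (p0, p1, p2) for the thirteen mSEGA items in
# an autonomous ambulatory 65+ population: heavier scoring on age, comorbidity
# and medication items, lighter on nutrition and meals; the overall level was
# calibrated (scripts/calibrate_simulator.py) jointly with the loadings so the
# generated mSEGA-frailty prevalence lands near the published 19.6%.
_MSEGA_MARGINALS: dict[str, tuple[float, float, float]] = {
    "age": (0.5325, 0.357, 0.1105),
    "provenance": (0.762, 0.187, 0.051),
    "medications": (0.5325, 0.255, 0.2125),
    "mood": (0.7025, 0.2125, 0.085),
    "perception_of_health": (0.745, 0.187, 0.068),
    "fall_6_months": (0.8555, 0.102, 0.0425),
    "nutrition": (0.83, 0.1275, 0.0425),
    "sicknesses": (0.49, 0.34, 0.17),
    "iadl": (0.66, 0.238, 0.102),
    "mobility": (0.66, 0.255, 0.085),
    "continence": (0.7875, 0.153, 0.0595),
    "meals": (0.83, 0.1275, 0.0425),
    "cognition": (0.728, 0.204, 0.068),
}

_MSEGA_LOADINGS = {
    "age": 0.600,
    "provenance": 0.674,
    "medications": 0.713,
    "mood": 0.540,
    "perception_of_health": 0.660,
    "fall_6_months": 0.600,
    "nutrition": 0.480,
    "sicknesses": 0.660,
    "iadl": 0.840,
    "mobility": 0.840,
    "continence": 0.540,
    "meals": 0.600,
    "cognition": 0.660,
}

_TWIN_PAIRS = (
    TwinPair("weight_loss_ge5pct_6mo", "nutrition", rho=0.85),
    TwinPair("home_aid_present", "provenance", rho=0.72),
    TwinPair("memory_complaint", "cognition", rho=0.62),
    TwinPair("polypharmacy_ge5_classes", "medications", rho=0.68),
    TwinPair("monopodal_stance_lt5s", "mobility", rho=0.40),
)


def default_spec(n: int = 102, seed: int = 0) -> SimSpec:
    """The emulated validation cohort: published marginals and demographics.

    Item prevalences and demographic moments come straight from the published
    cohort summaries; loadings and twin couplings are the calibrated defaults
    described in the module docstring.
    """
    items = tuple(
        ItemSpec(name, "zfs", "binary", _ZFS_MARGINALS[name], _ZFS_LOADINGS[name])
        for name in ZFS_ITEMS
    ) + tuple(
        ItemSpec(name, "msega", "ordinal3", _MSEGA_MARGINALS[name], _MSEGA_LOADINGS[name])
        for name in MSEGA_ITEMS
    )
    demo = dict(reference.cohort_demographics())
    sex = reference.sex_counts()
    spec = SimSpec(
        n=n,
        seed=seed,
        items=items,
        twin_pairs=_TWIN_PAIRS,
        demographics=demo,
        age_loading=0.35,
        sex_female_p=sex["female"] / (sex["female"] + sex["male"]),
    )
    spec.validate()
    return spec


def load_spec_config(path, n: Optional[int] = None, seed: Optional[int] = None) -> SimSpec:
    """Build a spec from a plain-text key-value config of overrides to the default.

    Lines are ``key = value``; ``#`` starts a comment.  Recognised keys:

    ==========================  ==================================================
    ``n`` / ``seed``            cohort size / random seed (integers)
    ``loading.<item>``          factor loading for one item (float in [0, 1))
    ``marginal.<item>``         prevalence p, or ``p0,p1,p2`` for ordinal items
    ``rho.<zfs_item>``          residual coupling of the twin pair anchored there
    ``age_loading``             loading of age on the latent factor
    ``sex_female_p``            probability of female sex
    ``demographic.<name>``      ``mean,sd`` for one numeric demographic
    ==========================  ==================================================

    ``n`` and ``seed`` arguments to this function override the file.
    """
    text = Path(path).read_text(encoding="utf-8")
    overrides: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        overrides[key] = value

    base = default_spec()
    spec_n = int(overrides.pop("n", base.n))
    spec_seed = int(overrides.pop("seed", base.seed))
    age_loading = float(overrides.pop("age_loading", base.age_loading))
    sex_female_p = float(overrides.pop("sex_female_p", base.sex_female_p))

    items = {it.name: it for it in base.items}
    pairs = {p.zfs_item: p for p in base.twin_pairs}
    demographics = dict(base.demographics)
    for key, value in overrides.items():
        prefix, _, name = key.partition(".")
        if prefix == "loading" and name in items:
            items[name] = replace(items[name], loading=float(value))
        elif prefix == "marginal" and name in items:
            parts = [float(v) for v in value.split(",")]
            marginal = parts[0] if len(parts) == 1 else tuple(parts)
            items[name] = replace(items[name], marginal=marginal)
        elif prefix == "rho" and name in pairs:
            pairs[name] = replace(pairs[name], rho=float(value))
        elif prefix == "demographic":
            mean, sd = (float(v) for v in value.split(","))
            demographics[name] = (mean, sd)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")

    spec = SimSpec(
        n=n if n is not None else spec_n,
        seed=seed if seed is not None else spec_seed,
        items=tuple(items[it.name] for it in base.items),
        twin_pairs=tuple(pairs[p.zfs_item] for p in base.twin_pairs),
        demographics=demographics,
        age_loading=age_loading,
        sex_female_p=sex_female_p,
    )
    spec.validate()
    return spec
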