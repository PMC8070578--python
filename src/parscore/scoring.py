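"""PAR component scoring and UK-weighted totals.

The PAR index converts raw occlusal traits into small integer scores per
component, then forms a weighted sum.  The component set and UK weights are

====================  =======================================  ======
component             trait scores                             weight
====================  =======================================  ======
anterior (per arch)   contact displacement 0-4, impacted 5       x1
posterior (per side)  sagittal 0-2 + vertical 0-1 + transv 0-4   x1
overjet               overjet 0-4 + anterior crossbite 0-4       x6
overbite              overlap 0-3 or open bite 0-4               x2
centerline            midline deviation 0-2                      x4
====================  =======================================  ======

The mm breakpoints behind the integer scores are not part of the index table
itself; the defaults here follow Richmond's published UK conventions and are
shipped as an editable, YAML-serialisable :class:`ThresholdTable` so a user
can audit or replace them.

Boundary handling: mm measurements are rounded to 0.1 mm (half away from
zero) before lookup and interval upper bounds are inclusive, so "1.1-2 mm"
means 1.05 <= d < 2.05 in raw measurement terms.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field, asdict

import yaml

from .errors import DomainError
from .geometry import TraitMeasurements

COMPONENT_FIELDS = (
    "anterior_upper",
    "anterior_lower",
    "posterior",
    "overjet",
    "overbite",
    "centerline",
)

_COMPONENT_RANGE_PER_UNIT = {  # max score of one scoring unit, for validation
    "posterior": 14,  # 2 sides x (2 + 1 + 4)
    "overjet": 8,  # overjet 0-4 + anterior crossbite 0-4
    "overbite": 4,
    "centerline": 2,
}


def round_mm(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used before table lookup."""
    scale = 10.0**decimals
    return math.floor(abs(value) * scale + 0.5) / scale * (1.0 if value >= 0 else -1.0)


def _lookup(value: float, intervals: tuple[tuple[float, int], ...]) -> int:
    """First interval whose inclusive upper bound is >= value."""
    for bound, score in intervals:
        if value <= bound:
            return score
    return intervals[-1][1]


@dataclass(frozen=True)
class ComponentScores:
    anterior_upper: int
    anterior_lower: int
    posterior: int
    overjet: int
    overbite: int
    centerline: int

    def __post_init__(self):
        for name in COMPONENT_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 0:
                raise DomainError(f"component {name} must be a non-negative integer, got {v!r}")
        for name, hi in _COMPONENT_RANGE_PER_UNIT.items():
            if getattr(self, name) > hi:
                raise DomainError(f"component {name} exceeds its maximum {hi}")

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in COMPONENT_FIELDS}


@dataclass(frozen=True)
class WeightScheme:
    """Per-component integer multipliers (default: UK weighting)."""

    name: str
    weights: dict[str, int]

    def __post_init__(self):
        missing = set(COMPONENT_FIELDS) - set(self.weights)
        if missing:
            raise DomainError(f"weight scheme {self.name!r} missing components {missing}")
        if any(w < 1 for w in self.weights.values()):
            raise DomainError("all weights must be >= 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump({"name": self.name, "weights": dict(self.weights)}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "WeightScheme":
        d = yaml.safe_load(text)
        return cls(name=d["name"], weights={k: int(v) for k, v in d["weights"].items()})


UK_WEIGHTS = WeightScheme(
    name="uk",
    weights={
        "anterior_upper": 1,
        "anterior_lower": 1,
        "posterior": 1,
        "overjet": 6,
        "overbite": 2,
        "centerline": 4,
    },
)


def _check_increasing(name, intervals):
    bounds = [b for b, _ in intervals]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise DomainError(f"{name} breakpoints must be strictly increasing")


@dataclass
class ThresholdTable:
    """Measurement -> integer score breakpoints for every PAR trait.

    Interval tables are ``((upper_bound, score), ...)`` with inclusive upper
    bounds after 0.1 mm rounding; the final entry's bound is ``inf``.
    Overbite overlap is assessed as *coverage* of the lower central incisor:
    the signed overlap in mm is divided by ``lower_incisor_crown_height_mm``
    and looked up in thirds-of-coverage bands.
    """

    displacement_mm: tuple = ((1.0, 0), (2.0, 1), (4.0, 2), (8.0, 3), (math.inf, 4))
    overjet_mm: tuple = ((3.0, 0), (5.0, 1), (7.0, 2), (9.0, 3), (math.inf, 4))
    open_bite_mm: tuple = ((0.0, 0), (1.0, 1), (2.0, 2), (3.0, 3), (math.inf, 4))
    overbite_coverage: tuple = (
        (1.0 / 3.0, 0),
        (2.0 / 3.0, 1),
        (1.0 - 1e-9, 2),
        (math.inf, 3),
    )
    centerline_fraction: tuple = ((0.25, 0), (0.5, 1), (math.inf, 2))
    #: impacted incisor/canine contributes this score per tooth
    impacted_score: int = 5
    #: anterior crossbite: number of teeth in crossbite -> score
    anterior_crossbite_counts: dict = field(default_factory=lambda: {0: 0, 1: 2, 2: 3})
    anterior_crossbite_default: int = 4
    lower_incisor_crown_height_mm: float = 9.0

    def __post_init__(self):
        for name in ("displacement_mm", "overjet_mm", "open_bite_mm", "overbite_coverage", "centerline_fraction"):
            _check_increasing(name, getattr(self, name))
        if self.lower_incisor_crown_height_mm <= 0:
            raise DomainError("crown height must be positive")

    # -- serialisation ------------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        for name in ("displacement_mm", "overjet_mm", "open_bite_mm", "overbite_coverage", "centerline_fraction"):
            d[name] = [[float(b), int(s)] for b, s in d[name]]
        d["anterior_crossbite_counts"] = {int(k): int(v) for k, v in d["anterior_crossbite_counts"].items()}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ThresholdTable":
        d = yaml.safe_load(text)
        for name in ("displacement_mm", "overjet_mm", "open_bite_mm", "overbite_coverage", "centerline_fraction"):
            if name in d:
                d[name] = tuple((float(b), int(s)) for b, s in d[name])
        if "anterior_crossbite_counts" in d:
            d["anterior_crossbite_counts"] = {int(k): int(v) for k, v in d["anterior_crossbite_counts"].items()}
        return cls(**d)

    # -- per-trait lookups --------------------------------------------------
    def crossbite_score(self, n_teeth: int) -> int:
        return self.anterior_crossbite_counts.get(int(n_teeth), self.anterior_crossbite_default)


@dataclass(frozen=True)
class PARScore:
    components: ComponentScores
    scheme: WeightScheme
    unweighted_total: int
    weighted_total: int

    def weighted_components(self) -> dict[str, int]:
        """Per-component score x weight, the convention of published PAR tables."""
        return {
            name: getattr(self.components, name) * self.scheme.weights[name]
            for name in COMPONENT_FIELDS
        }


def score_displacement(d_mm: float, impacted: bool = False, thresholds: ThresholdTable | None = None) -> int:
    """Score one contact-point displacement (impaction overrides the lookup)."""
    t = thresholds or ThresholdTable()
    if impacted:
        return t.impacted_score
    if d_mm < 0:
        raise DomainError(f"displacement must be non-negative, got {d_mm}")
    return _lookup(round_mm(d_mm), t.displacement_mm)


def score_component(traits: TraitMeasurements, thresholds: ThresholdTable | None = None) -> ComponentScores:
    """Map raw trait measurements to the six PAR component scores."""
    t = thresholds or ThresholdTable()

    anterior = {"upper_anterior": 0, "lower_anterior": 0}
    for cd in traits.contact_displacements:
        if cd.segment not in anterior:
            raise DomainError(f"unknown displacement segment {cd.segment!r}")
        anterior[cd.segment] += score_displacement(cd.value_mm, thresholds=t)
    for segment, n in traits.impacted_teeth.items():
        if segment not in anterior:
            raise DomainError(f"unknown impaction segment {segment!r}")
        anterior[segment] += t.impacted_score * int(n)

    posterior = 0
    for side, cats in traits.posterior.items():
        if side not in ("left", "right"):
            raise DomainError(f"unknown posterior side {side!r}")
        posterior += cats.sagittal + cats.vertical + cats.transverse

    overjet = _lookup(round_mm(traits.overjet_mm), t.overjet_mm)
    overjet += t.crossbite_score(traits.anterior_crossbite_teeth)

    overlap = traits.overbite_overlap_mm
    if overlap >= 0:
        coverage = round_mm(overlap) / t.lower_incisor_crown_height_mm
        overbite = _lookup(coverage, t.overbite_coverage)
    else:
        overbite = _lookup(round_mm(-overlap), t.open_bite_mm)

    centerline = _lookup(traits.centerline_fraction, t.centerline_fraction)

    return ComponentScores(
        anterior_upper=anterior["upper_anterior"],
        anterior_lower=anterior["lower_anterior"],
        posterior=posterior,
        overjet=overjet,
        overbite=overbite,
        centerline=centerline,
    )


def weighted_total(components: ComponentScores, scheme: WeightScheme = UK_WEIGHTS) -> PARScore:
    """Sum-product of component scores and weights; records both totals."""
    unweighted = sum(components.as_dict().values())
    weighted = sum(v * scheme.weights[k] for k, v in components.as_dict().items())
    return PARScore(components, scheme, unweighted, weighted)


def score_traits(
    traits: TraitMeasurements,
    thresholds: ThresholdTable | None = None,
    scheme: WeightScheme = UK_WEIGHTS,
) -> PARScore:
    """Convenience: traits -> components -> weighted PAR score."""
    return weighted_total(score_component(traits, thresholds), scheme)
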