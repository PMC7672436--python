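"""The study's system catalog: sequence classes, symmetry-reduced
enumeration of central-pair systems, and counterion arithmetic.

Annotation convention: ``(a/s)X/(a/s)Y`` for mismatches and ``aX:aY`` for
the canonical pairs, with the purine written first (alphabetical within a
purine/purine or pyrimidine/pyrimidine pair, anti before syn when the two
bases are identical).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import CatalogError, ConfigurationError

__all__ = ["SequenceClass", "SystemSpec", "load_catalog", "enumerate_systems",
           "catalog_total", "counterion_count", "load_propensity_table"]

BASES = ("A", "C", "G", "T")
ORIENTATION_FAMILIES = (("anti", "anti"), ("anti", "syn"), ("syn", "anti"))
_CANONICAL = {frozenset(("A", "T")), frozenset(("G", "C"))}
_PURINES = {"A", "G"}


@dataclass(frozen=True)
class SystemSpec:
    class_name: str
    x: str
    y: str
    orientation_x: str
    orientation_y: str

    @property
    def canonical(self) -> bool:
        return (self.orientation_x == self.orientation_y == "anti"
                and frozenset((self.x, self.y)) in _CANONICAL)

    @property
    def annotation(self) -> str:
        sep = ":" if self.canonical else "/"
        ox = self.orientation_x[0]
        oy = self.orientation_y[0]
        return f"{ox}{self.x}{sep}{oy}{self.y}"


@dataclass
class SequenceClass:
    name: str
    chain_a: str
    chain_b: str
    palindromic: bool
    systems: list | None = None
    comment: str = ""
    p_value: float | None = None
    central_context: str = ""

    def __post_init__(self):
        if len(self.chain_a) != len(self.chain_b):
            raise ConfigurationError(f"class {self.name}: chain lengths differ")
        n = len(self.chain_a)
        if self.chain_a[n // 2] != "X" or self.chain_b[n // 2] != "Y":
            raise ConfigurationError(
                f"class {self.name}: X/Y placeholder must sit centrally")

    @property
    def length(self) -> int:
        return len(self.chain_a)


def load_catalog() -> dict[str, SequenceClass]:
    """The packaged sequence-class catalog keyed by class name."""
    text = resources.files("pairscape.data").joinpath("catalog.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, c in raw["classes"].items():
        out[str(name)] = SequenceClass(
            name=str(name), chain_a=c["chain_a"], chain_b=c["chain_b"],
            palindromic=bool(c.get("palindromic", False)),
            systems=c.get("systems"), comment=c.get("comment", ""),
            p_value=c.get("p_value"),
            central_context=c.get("central_context", ""))
    return out


def published_class_I_annotations() -> list[str]:
    text = resources.files("pairscape.data").joinpath("catalog.yaml").read_text()
    raw = yaml.safe_load(text)["class_I_systems"]
    return raw["anti_anti"] + raw["anti_syn"] + raw["syn_anti"]


def _parse_annotation(class_name: str, ann: str) -> SystemSpec:
    sep = ":" if ":" in ann else "/"
    left, right = ann.split(sep)
    omap = {"a": "anti", "s": "syn"}
    return SystemSpec(class_name, left[1], right[1],
                      omap[left[0]], omap[right[0]])


def _representative(class_name: str, x: str, y: str,
                    ox: str, oy: str) -> SystemSpec:
    """Canonical member of the strand-swap equivalence class.

    (X, Y, o1/o2) ~ (Y, X, o2/o1); the kept spelling orders the purine first
    (alphabetical within the same ring family; anti first on identical bases).
    """
    def key(base, orient):
        return (0 if base in _PURINES else 1, base, 0 if orient == "anti" else 1)
    a = (x, ox)
    b = (y, oy)
    if key(*b) < key(*a):
        a, b = b, a
    return SystemSpec(class_name, a[0], b[0], a[1], b[1])


def enumerate_systems(cls: SequenceClass,
                      deduplicate: bool = True) -> list[SystemSpec]:
    """All central-pair systems of a class.

    Palindromic classes enumerate the 16 X/Y combinations in the three
    orientation families (syn/syn excluded) and, when ``deduplicate``,
    reduce the 48 candidates by the palindromic strand-swap equivalence.
    Non-palindromic classes return their cataloged system list verbatim.
    """
    if not isinstance(cls, SequenceClass):
        raise CatalogError("enumerate_systems expects a SequenceClass")
    if not cls.palindromic:
        if not cls.systems:
            raise CatalogError(f"class {cls.name} lists no systems")
        return [_parse_annotation(cls.name, a) for a in cls.systems]
    out = []
    seen = set()
    for ox, oy in ORIENTATION_FAMILIES:
        for x in BASES:
            for y in BASES:
                if deduplicate:
                    spec = _representative(cls.name, x, y, ox, oy)
                    if spec in seen:
                        continue
                    seen.add(spec)
                else:
                    spec = SystemSpec(cls.name, x, y, ox, oy)
                out.append(spec)
    return out


def catalog_total(catalog: dict | None = None) -> int:
    """Total number of unique systems across all cataloged classes."""
    if catalog is None:
        catalog = load_catalog()
    return sum(len(enumerate_systems(c)) for c in catalog.values())


def counterion_count(duplex_length_nt: int,
                     five_prime_phosphate: bool = False) -> int:
    """Monovalent cations neutralizing a blunt duplex.

    Each strand carries length-1 phosphates (length with a 5' phosphate),
    one negative charge each.
    """
    if duplex_length_nt < 2:
        raise CatalogError("duplex length must be at least 2")
    per_strand = duplex_length_nt if five_prime_phosphate \
        else duplex_length_nt - 1
    return 2 * per_strand


def load_propensity_table() -> dict:
    """Published opening propensities at delta-Opening = -60 deg.

    Returns {"delta_sigma": float, "propensities": {class: {pair: (value,
    stderr)}}}; reference inputs for downstream gap arithmetic.
    """
    text = resources.files("pairscape.data").joinpath(
        "opening_propensities.yaml").read_text()
    raw = yaml.safe_load(text)
    table = {cls: {bp: (float(v[0]), float(v[1])) for bp, v in d.items()}
             for cls, d in raw["propensities"].items()}
    return {"delta_sigma": float(raw["delta_sigma"]), "propensities": table}
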