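"""Exact combinatorial engine for gamete formation, selfing and band
phenotypes in tetraploids.

Two inheritance modes are modelled for a tetraploid parent scored with a
codominant (e.g. SSR) marker:

* **tetrasomic** — all four homologous chromosomes segregate randomly
  ("random chromosome segregation"); a gamete receives an unordered pair
  of the four chromosomes, optionally with a double-reduction component.
  Selfing a duplex heterozygote ``AAaa`` yields the classic 1:34:1
  band-phenotype ratio, a simplex ``Aaaa`` yields 3:1, a triplex ``AAAa``
  yields 1:3.
* **disomic** — strict preferential (bivalent) pairing within subgenomes;
  each subgenome locus segregates like an independent diploid locus, so a
  heterozygous locus ``Aa`` selfs to 1:2:1.

All probabilities are :class:`fractions.Fraction`; every distribution sums
to exactly 1 with no tolerance. Band *phenotypes* are sets of distinct band
labels: a homozygote shows one band, a heterozygote several. An explicit
alias map handles the case where alleles from different subgenomes comigrate
(equal band size), which is what turns the two-locus ``Aa/Bb`` selfing into
the 1:14:1 single-marker ratio.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence, Union

from .errors import InvalidGenotypeError, MappingError

__all__ = [
    "allele_sort_key",
    "TetrasomicGenotype",
    "DisomicGenotype",
    "ParentModel",
    "tetrasomic_gametes",
    "disomic_gametes",
    "self_progeny",
    "collapse_phenotypes",
    "render_phenotype",
    "render_genotype",
    "expected_integer_ratio",
    "dual_subgenome_catalog",
    "DualSubgenomeEntry",
    "check_distribution",
    "distribution_to_jsonable",
]

# Maximum double-reduction rate under complete equational segregation.
MAX_DOUBLE_REDUCTION = Fraction(1, 6)


def allele_sort_key(label: str) -> tuple[str, int]:
    """Total order on allele/band labels.

    Bands are labelled by decreasing size: at a two-allele locus the upper
    band is the capital letter (``A`` before ``a``); at a multi-allele locus
    ``a`` > ``b`` > ``c`` > ``d``. The key sorts same-letter capitals first,
    then letters alphabetically, so phenotype classes come out in the
    conventional (upper homozygote, heterozygote, lower homozygote) order.
    """
    return (label.lower(), 0 if label.isupper() else 1)


def _sorted_alleles(alleles: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(alleles, key=allele_sort_key))


Gamete = tuple[str, ...]
Genotype = tuple[str, ...]
Phenotype = frozenset
Distribution = dict


@dataclass(frozen=True)
class TetrasomicGenotype:
    """A tetraploid genotype at one locus: a multiset of exactly 4 alleles."""

    alleles: tuple[str, ...]

    def __init__(self, alleles: Iterable[str]):
        object.__setattr__(self, "alleles", _sorted_alleles(alleles))
        if len(self.alleles) != 4:
            raise InvalidGenotypeError(
                f"tetrasomic genotype needs exactly 4 alleles, got {self.alleles!r}"
            )

    @classmethod
    def from_string(cls, s: str) -> "TetrasomicGenotype":
        return cls(tuple(s))

    def allele_set(self) -> frozenset:
        return frozenset(self.alleles)

    def __str__(self) -> str:
        return "".join(self.alleles)


@dataclass(frozen=True)
class DisomicGenotype:
    """A list of independent subgenome loci, each with exactly 2 alleles."""

    loci: tuple[tuple[str, str], ...]

    def __init__(self, loci: Iterable[Iterable[str]]):
        canon = tuple(_sorted_alleles(locus) for locus in loci)
        object.__setattr__(self, "loci", canon)
        if not self.loci:
            raise InvalidGenotypeError("disomic genotype needs at least one locus")
        for locus in self.loci:
            if len(locus) != 2:
                raise InvalidGenotypeError(
                    f"each subgenome locus needs exactly 2 alleles, got {locus!r}"
                )

    @classmethod
    def from_string(cls, s: str) -> "DisomicGenotype":
        """Parse ``"Aa"`` or ``"AB;CD"`` (``;`` or ``/`` separate loci)."""
        parts = s.replace("/", ";").split(";")
        return cls(tuple(tuple(p) for p in parts))

    def allele_set(self) -> frozenset:
        return frozenset(a for locus in self.loci for a in locus)

    def __str__(self) -> str:
        return ";".join("".join(locus) for locus in self.loci)


def _as_double_reduction(value) -> Fraction:
    alpha = Fraction(value)
    if not 0 <= alpha <= MAX_DOUBLE_REDUCTION:
        raise ValueError(
            f"double_reduction must lie in [0, 1/6], got {alpha}"
        )
    return alpha


@dataclass(frozen=True)
class ParentModel:
    """A parental segregation hypothesis: genotype + mode + band aliasing.

    ``alias`` maps allele labels to band labels (many-to-one allowed); the
    identity map is the default. ``double_reduction`` is only meaningful in
    tetrasomic mode and defaults to 0 (pure random chromosome segregation),
    the value under which all the classic ratios hold.
    """

    mode: str
    genotype: Union[TetrasomicGenotype, DisomicGenotype]
    alias: Mapping[str, str] = field(default_factory=dict)
    double_reduction: Fraction = Fraction(0)

    def __post_init__(self):
        if self.mode not in ("disomic", "tetrasomic"):
            raise ValueError(f"unknown inheritance mode {self.mode!r}")
        if self.mode == "tetrasomic" and not isinstance(self.genotype, TetrasomicGenotype):
            raise InvalidGenotypeError("tetrasomic mode requires a TetrasomicGenotype")
        if self.mode == "disomic":
            if not isinstance(self.genotype, DisomicGenotype):
                raise InvalidGenotypeError("disomic mode requires a DisomicGenotype")
            if self.double_reduction != 0:
                raise ValueError("double_reduction must be 0 under disomic inheritance")
        object.__setattr__(
            self, "double_reduction", _as_double_reduction(self.double_reduction)
        )

    @classmethod
    def from_spec(cls, spec: str, alias: Mapping[str, str] | None = None,
                  double_reduction=0) -> "ParentModel":
        """Build from a ``"mode:genotype"`` string, e.g. ``"disomic:Aa"``,
        ``"tetrasomic:AAaa"``, ``"disomic:AB;CD"``."""
        try:
            mode, geno = spec.split(":", 1)
        except ValueError:
            raise ValueError(f"model spec {spec!r} is not of the form mode:genotype")
        mode = mode.strip().lower()
        geno = geno.strip()
        if mode == "tetrasomic":
            g: Union[TetrasomicGenotype, DisomicGenotype] = TetrasomicGenotype.from_string(geno)
        elif mode == "disomic":
            g = DisomicGenotype.from_string(geno)
        else:
            raise ValueError(f"unknown inheritance mode {mode!r}")
        return cls(mode=mode, genotype=g, alias=dict(alias or {}),
                   double_reduction=Fraction(double_reduction))

    def resolved_alias(self) -> dict:
        """Alias map completed with identity for unlisted alleles."""
        out = {a: a for a in self.genotype.allele_set()}
        out.update(self.alias)
        return out

    def band_alphabet(self) -> frozenset:
        alias = self.resolved_alias()
        return frozenset(alias[a] for a in self.genotype.allele_set())

    def gametes(self) -> Distribution:
        if self.mode == "tetrasomic":
            return tetrasomic_gametes(self.genotype, self.double_reduction)
        return disomic_gametes(self.genotype)

    def selfed_genotypes(self) -> Distribution:
        return self_progeny(self.gametes())

    def phenotypes(self) -> Distribution:
        return collapse_phenotypes(self.selfed_genotypes(), self.resolved_alias())

    def phenotype_classes(self) -> list[str]:
        """Canonical phenotype strings in (upper, ..., lower) display order."""
        dist = self.phenotypes()
        alphabet = self.band_alphabet()
        keys = sorted(dist, key=lambda b: tuple(allele_sort_key(x) for x in _sorted_alleles(b)))
        return [render_phenotype(k, alphabet) for k in keys]

    def class_probs(self) -> dict[str, Fraction]:
        """Phenotype distribution keyed by canonical phenotype strings."""
        dist = self.phenotypes()
        alphabet = self.band_alphabet()
        return {render_phenotype(k, alphabet): v for k, v in dist.items()}


def check_distribution(dist: Mapping) -> None:
    """Assert exact normalization and non-negativity."""
    total = sum(dist.values(), Fraction(0))
    if total != 1:
        raise ValueError(f"distribution sums to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError("distribution has a negative probability")


def tetrasomic_gametes(genotype: TetrasomicGenotype, double_reduction=0) -> Distribution:
    """Gamete distribution of a tetrasomic parent.

    With probability 1−α the gamete is an unordered pair of 2 of the 4
    chromosomes, all C(4,2)=6 pairs equally likely (random chromosome
    segregation); with probability α it is a doubled copy of one of the 4
    chromosomes, chosen uniformly (double reduction). α defaults to 0.
    """
    if not isinstance(genotype, TetrasomicGenotype):
        genotype = TetrasomicGenotype(genotype)
    alpha = _as_double_reduction(double_reduction)
    dist: Distribution = defaultdict(Fraction)
    chroms = genotype.alleles
    for i, j in combinations(range(4), 2):
        dist[_sorted_alleles((chroms[i], chroms[j]))] += (1 - alpha) * Fraction(1, 6)
    if alpha > 0:
        for c in chroms:
            dist[(c, c)] += alpha * Fraction(1, 4)
    out = {k: v for k, v in dist.items() if v > 0}
    check_distribution(out)
    return out


def disomic_gametes(genotype: DisomicGenotype) -> Distribution:
    """Gamete distribution of a disomic parent: each subgenome locus
    independently transmits one of its two alleles with probability 1/2;
    the gamete is the tuple of transmitted alleles, one per locus."""
    if not isinstance(genotype, DisomicGenotype):
        genotype = DisomicGenotype(genotype)
    dist: Distribution = defaultdict(Fraction)
    n_loci = len(genotype.loci)
    for choice in product(*genotype.loci):
        dist[tuple(choice)] += Fraction(1, 2) ** n_loci
    out = dict(dist)
    check_distribution(out)
    return out


def self_progeny(gametes: Mapping) -> Distribution:
    """Self-convolution of a gamete distribution.

    The zygote genotype is the sorted multiset union of the two gametes'
    alleles; this canonical form is shared by both modes (a disomic zygote's
    per-locus structure is recoverable from the parent model, and band
    phenotypes depend only on which alleles are present).
    """
    check_distribution(gametes)
    dist: Distribution = defaultdict(Fraction)
    for g1, p1 in gametes.items():
        for g2, p2 in gametes.items():
            dist[_sorted_alleles(g1 + g2)] += p1 * p2
    out = dict(dist)
    check_distribution(out)
    return out


def collapse_phenotypes(genotype_dist: Mapping, alias: Mapping[str, str] | None = None) -> Distribution:
    """Collapse a genotype distribution to band phenotypes.

    Each genotype maps to the set of distinct aliased band labels it shows
    on a gel; probabilities of genotypes with identical band sets are summed.
    ``alias`` defaults to the identity on every allele present.
    """
    check_distribution(genotype_dist)
    dist: Distribution = defaultdict(Fraction)
    for geno, p in genotype_dist.items():
        bands = set()
        for a in geno:
            if alias is not None and a not in alias:
                raise MappingError(f"allele {a!r} missing from alias map")
            bands.add(alias[a] if alias is not None else a)
        dist[frozenset(bands)] += p
    out = dict(dist)
    check_distribution(out)
    return out


def render_phenotype(bands: frozenset, alphabet: Iterable[str] | None = None) -> str:
    """Canonical string for a band set.

    At a two-band marker a single-band homozygote is written doubled
    (``"AA"``/``"aa"``); multi-band markers use the plain letter set
    (``"abc"``). ``alphabet`` is the full set of band labels the marker can
    show; doubling applies only when it has exactly two labels.
    """
    letters = _sorted_alleles(bands)
    if alphabet is not None and len(frozenset(alphabet)) == 2 and len(letters) == 1:
        return letters[0] * 2
    return "".join(letters)


def render_genotype(genotype: Sequence[str]) -> str:
    return "".join(_sorted_alleles(tuple(genotype)))


def expected_integer_ratio(dist: Mapping, class_order: Sequence | None = None) -> tuple[list, list[int]]:
    """Smallest coprime integer vector proportional to the probabilities.

    Returns ``(ordered_classes, integers)``. The default class order sorts
    band sets lexicographically under the band-size order, which puts the
    upper homozygote first and the lower homozygote last for 3-class
    markers (matching the conventional "1AA : 2Aa : 1aa" reading).
    """
    if class_order is None:
        class_order = sorted(
            dist, key=lambda b: tuple(allele_sort_key(x) for x in _sorted_alleles(b))
        )
    probs = [Fraction(dist[c]) for c in class_order]
    denom_lcm = math.lcm(*(p.denominator for p in probs)) if probs else 1
    ints = [int(p * denom_lcm) for p in probs]
    g = math.gcd(*ints) if ints else 1
    return list(class_order), [i // g for i in ints]


@dataclass(frozen=True)
class DualSubgenomeEntry:
    """One parental configuration of the dual-subgenome single-marker scenario."""

    name: str
    genotype: DisomicGenotype
    classes: tuple[str, ...]
    ratio: tuple[int, ...]
    segregating: bool


# Alias collapsing subgenome-B alleles onto the A-subgenome band sizes:
# A and B comigrate as the upper band, a and b as the lower band.
_DUAL_ALIAS = {"A": "A", "B": "A", "a": "a", "b": "a"}

_DUAL_CONFIGS = ["AA;Bb", "AA;bb", "Aa;BB", "Aa;Bb", "Aa;bb", "aa;BB", "aa;Bb"]


def dual_subgenome_catalog() -> list[DualSubgenomeEntry]:
    """All 7 two-band parental configurations when one SSR amplifies a locus
    in each subgenome and the two subgenomes' alleles comigrate (A=B upper,
    a=b lower). Selfing gives: 1:3 for AA/Bb and Aa/BB, no segregation for
    AA/bb and aa/BB, 1:14:1 for Aa/Bb, and 3:1 for Aa/bb and aa/Bb."""
    entries = []
    for cfg in _DUAL_CONFIGS:
        parent = ParentModel.from_spec("disomic:" + cfg, alias=_DUAL_ALIAS)
        dist = parent.phenotypes()
        keys, ints = expected_integer_ratio(dist)
        classes = tuple(render_phenotype(k, parent.band_alphabet()) for k in keys)
        entries.append(
            DualSubgenomeEntry(
                name=cfg.replace(";", "/"),
                genotype=parent.genotype,
                classes=classes,
                ratio=tuple(ints),
                segregating=len(ints) > 1,
            )
        )
    return entries


def fraction_three_to_one(catalog: list[DualSubgenomeEntry] | None = None) -> Fraction:
    """Fraction of dual-subgenome configurations whose selfing ratio is a
    two-class 3:1-type ratio (1:3 or 3:1)."""
    catalog = catalog if catalog is not None else dual_subgenome_catalog()
    hits = sum(1 for e in catalog if sorted(e.ratio) == [1, 3])
    return Fraction(hits, len(catalog))


def distribution_to_jsonable(dist: Mapping, alphabet: Iterable[str] | None = None) -> dict[str, str]:
    """Serialize a distribution with rational probabilities as "p/q" strings.

    Keys that are band sets render via :func:`render_phenotype`; tuple keys
    (gametes/genotypes) render as concatenated sorted letters.
    """
    out = {}
    for k, v in dist.items():
        if isinstance(k, frozenset):
            key = render_phenotype(k, alphabet)
        elif isinstance(k, tuple):
            key = render_genotype(k)
        else:
            key = str(k)
        v = Fraction(v)
        out[key] = f"{v.numerator}/{v.denominator}"
    return out
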