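"""Synthetic S1 marker populations with the statistical structure the
inference stage assumes.

A population of selfed progeny is drawn from a parent model's exact selfing
distribution, optionally reweighted by genotype-specific zygote viability
(the standard mechanism for segregation distortion: a marker linked to a
recessive lethal loses its homozygous class), masked to missing at a
uniform per-cell rate, and optionally contaminated with outcrossed progeny
sired by a second parent. Everything is reproducible from one integer
seed; each marker gets its own RNG stream derived by stable hashing of the
marker ID, so adding a marker never perturbs existing columns.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MISSING, MarkerTable
from .models import (
    ParentModel,
    collapse_phenotypes,
    render_genotype,
    render_phenotype,
)

__all__ = ["SimulationConfig", "simulate_s1_population", "expected_counts_table"]

# Default S1 population sizes mirroring the two study populations.
DEFAULT_N_ZEBRA = 228
DEFAULT_N_A12359 = 273


@dataclass
class SimulationConfig:
    """Parameters of one simulated S1 (selfed) population.

    ``viability`` maps zygote genotype strings (canonical sorted form, e.g.
    ``"AAaa"`` or ``"AAbb"``) to non-negative weights; unlisted genotypes
    weigh 1. ``outcross_rate`` > 0 requires ``other_parent`` and replaces a
    progeny with a parent x other_parent offspring (one gamete from each).
    """

    parent: ParentModel
    n_progeny: int = DEFAULT_N_ZEBRA
    missing_rate: float = 0.0
    viability: Mapping[str, float] = field(default_factory=dict)
    outcross_rate: float = 0.0
    other_parent: ParentModel | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_progeny < 0:
            raise ValidationError("n_progeny must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if not 0 <= self.outcross_rate < 1:
            raise ValidationError("outcross_rate must lie in [0, 1)")
        if self.outcross_rate > 0 and self.other_parent is None:
            raise ValidationError("outcross_rate > 0 requires other_parent")
        if any(w < 0 for w in self.viability.values()):
            raise ValidationError("viability weights must be >= 0")


def _marker_stream(seed: int, marker: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(marker.encode("utf-8"))])


def _band_alphabet(config: SimulationConfig) -> frozenset:
    """Band labels the table can show: union over both parents when
    outcrossing, so all cells render consistently."""
    alphabet = config.parent.band_alphabet()
    if config.other_parent is not None:
        alphabet |= config.other_parent.band_alphabet()
    return alphabet


def _viable_phenotype_support(config: SimulationConfig, alphabet: frozenset):
    """Selfing genotype distribution reweighted by viability, plus the
    rendered phenotype of each genotype."""
    geno_dist = config.parent.selfed_genotypes()
    alias = config.parent.resolved_alias()
    two_band = len(alphabet) == 2
    genotypes, weights, phenos = [], [], []
    for geno, p in geno_dist.items():
        name = render_genotype(geno)
        w = float(config.viability.get(name, 1.0))
        if w == 0.0:
            continue
        bands = frozenset(alias[a] for a in geno)
        genotypes.append(name)
        weights.append(float(p) * w)
        phenos.append(render_phenotype(bands, alphabet if two_band else None))
    total = sum(weights)
    if total == 0:
        raise ValidationError("viability weights remove every genotype")
    probs = np.asarray(weights) / total
    return genotypes, probs, phenos


def _outcross_phenotypes(config: SimulationConfig, alphabet: frozenset):
    """Phenotype support of parent x other_parent offspring."""
    assert config.other_parent is not None
    g1 = config.parent.gametes()
    g2 = config.other_parent.gametes()
    alias = dict(config.other_parent.resolved_alias())
    alias.update(config.parent.resolved_alias())  # self parent's entries win
    zygotes: dict = {}
    for a, pa in g1.items():
        for b, pb in g2.items():
            key = tuple(sorted(a + b))
            zygotes[key] = zygotes.get(key, Fraction(0)) + pa * pb
    pheno_dist = collapse_phenotypes(zygotes, alias)
    two_band = len(alphabet) == 2
    keys = list(pheno_dist)
    probs = np.asarray([float(pheno_dist[k]) for k in keys])
    names = [render_phenotype(k, alphabet if two_band else None) for k in keys]
    return names, probs / probs.sum()


def simulate_s1_population(
    config: SimulationConfig, markers: Sequence[str] = ("M1",)
) -> MarkerTable:
    """Draw a selfed progeny population and return it as a marker table.

    All markers share the configured parent model but are drawn from
    independent per-marker streams. Sample IDs are ``S0001``... and the
    parent is included as row ``PARENT`` (flagged, excluded from progeny
    tallies).
    """
    n = config.n_progeny
    alphabet = _band_alphabet(config)
    genotypes, probs, phenos = _viable_phenotype_support(config, alphabet)
    pheno_arr = np.asarray(phenos, dtype=object)
    if config.outcross_rate > 0:
        oc_names, oc_probs = _outcross_phenotypes(config, alphabet)
        oc_arr = np.asarray(oc_names, dtype=object)

    columns = {}
    for marker in markers:
        rng = _marker_stream(config.seed, marker)
        cells = pheno_arr[rng.choice(len(pheno_arr), size=n, p=probs)]
        if config.outcross_rate > 0:
            is_oc = rng.random(n) < config.outcross_rate
            if is_oc.any():
                cells = cells.copy()
                cells[is_oc] = oc_arr[
                    rng.choice(len(oc_arr), size=int(is_oc.sum()), p=oc_probs)
                ]
        if config.missing_rate > 0:
            mask = rng.random(n) < config.missing_rate
            cells = cells.copy()
            cells[mask] = MISSING
        columns[marker] = cells

    parent_pheno = render_phenotype(
        frozenset(config.parent.resolved_alias()[a]
                  for a in config.parent.genotype.allele_set()),
        alphabet if len(alphabet) == 2 else None,
    )
    sample_ids = ["PARENT"] + [f"S{i + 1:04d}" for i in range(n)]
    data = {
        m: np.concatenate(([parent_pheno], col)) for m, col in columns.items()
    }
    df = pd.DataFrame(data, index=sample_ids, dtype=object)[list(markers)]
    return MarkerTable(data=df, parent_ids=("PARENT",))


def expected_counts_table(parent: ParentModel, n: int) -> pd.DataFrame:
    """Expected phenotype counts for n selfed progeny of a parent model.

    Columns: phenotype class, exact probability ("p/q"), exact expected
    count ("p/q"), float expectation, and the one-decimal rounding used in
    printed tables.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    probs = parent.class_probs()
    rows = []
    for cls in parent.phenotype_classes():
        p = probs[cls]
        exact = p * n
        rows.append(
            {
                "class": cls,
                "probability": f"{p.numerator}/{p.denominator}",
                "expected_exact": f"{exact.numerator}/{exact.denominator}",
                "expected": float(exact),
                "expected_1dp": round(float(exact), 1),
            }
        )
    return pd.DataFrame(rows)
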