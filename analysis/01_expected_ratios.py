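#!/usr/bin/env python
"""Enumerate the expected S1 segregation ratios under every parental
hypothesis relevant to a two-band or four-band SSR in a tetraploid, and
the dual-subgenome catalogue. Writes results/expected_ratios.json."""

import json
from pathlib import Path

from polyseg.models import (
    ParentModel,
    distribution_to_jsonable,
    dual_subgenome_catalog,
    expected_integer_ratio,
    fraction_three_to_one,
    render_phenotype,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def ratio_entry(spec, alias=None):
    parent = ParentModel.from_spec(spec, alias=alias or {})
    dist = parent.phenotypes()
    keys, ints = expected_integer_ratio(dist)
    classes = [render_phenotype(k, parent.band_alphabet()) for k in keys]
    return {
        "classes": classes,
        "ratio": ints,
        "distribution": distribution_to_jsonable(dist, parent.band_alphabet()),
    }


def main():
    out = {
        "two_band_hypotheses": {
            "disomic Aa": ratio_entry("disomic:Aa"),
            "tetrasomic AAAa": ratio_entry("tetrasomic:AAAa"),
            "tetrasomic AAaa": ratio_entry("tetrasomic:AAaa"),
            "tetrasomic Aaaa": ratio_entry("tetrasomic:Aaaa"),
        },
        "four_band_hypotheses": {
            "tetrasomic ABCD": ratio_entry("tetrasomic:abcd"),
            "disomic ab & cd": ratio_entry("disomic:ab;cd"),
        },
        "dual_subgenome_catalog": [
            {"config": e.name, "classes": list(e.classes),
             "ratio": list(e.ratio), "segregating": e.segregating}
            for e in dual_subgenome_catalog()
        ],
    }
    abcd = ParentModel.from_spec("tetrasomic:abcd")
    out["abcd_selfing"] = {
        "n_genotypes": len(abcd.selfed_genotypes()),
        "n_phenotypes": len(abcd.phenotypes()),
    }
    frac = fraction_three_to_one()
    out["dual_subgenome_three_to_one_fraction"] = f"{frac.numerator}/{frac.denominator}"

    OUT.mkdir(exist_ok=True)
    with open(OUT / "expected_ratios.json", "w") as fh:
        json.dump(out, fh, indent=2)

    print("Selfing a duplex tetrasomic heterozygote gives",
          ":".join(map(str, out["two_band_hypotheses"]["tetrasomic AAaa"]["ratio"])),
          "band phenotypes; a disomic heterozygote gives 1:2:1.")
    print("Tetrasomic ABCD selfing:", out["abcd_selfing"]["n_genotypes"],
          "genotypes collapsing to", out["abcd_selfing"]["n_phenotypes"], "phenotypes;")
    print("two independent disomic loci give",
          len(out["four_band_hypotheses"]["disomic ab & cd"]["classes"]), "phenotypes.")
    print("Dual-subgenome single-marker catalogue: 7 configurations,",
          out["dual_subgenome_three_to_one_fraction"], "with a 3:1-type ratio.")
    print("Wrote", OUT / "expected_ratios.json")


if __name__ == "__main__":
    main()
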