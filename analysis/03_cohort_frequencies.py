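"""Allele-frequency table for the Swedish survey cohorts with exact CIs.

Takes the published cohort sizes and marker counts (Cs29 allele copies of
2n, Cs6-positive animals of n), computes Clopper-Pearson 95% intervals, and
writes the frequency table plus an aligned text rendering.

Run from the repository root:  python analysis/03_cohort_frequencies.py
"""

from cside.datasets import SWEDISH_COHORTS, WGS_DEPTH_COHORT
from cside.popgen_stats import (
    allele_freq_codominant,
    format_survey_report,
    survey_report,
)

OUT = "results/allele_frequency_table.csv"


def main() -> None:
    report = survey_report(SWEDISH_COHORTS)
    report.to_csv(OUT, index=False)
    print(format_survey_report(report))

    wgs = allele_freq_codominant(
        WGS_DEPTH_COHORT["hom"], WGS_DEPTH_COHORT["het"], WGS_DEPTH_COHORT["non-carrier"]
    )
    print(
        f"\nsequenced cohort ({sum(WGS_DEPTH_COHORT.values())} animals, "
        f"{WGS_DEPTH_COHORT['hom']} hom + {WGS_DEPTH_COHORT['het']} het): "
        f"Cs29 allele frequency {wgs.display()}"
    )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
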