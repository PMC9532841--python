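#!/usr/bin/env python
"""Mass-spectrometric verification of the synthetic peptide identities.

Computes theoretical average/monoisotopic masses and singly charged b/y
fragment ladders for the four study peptides and matches the observed
parental ions from the MALDI spectra against theory at 0.5 Da tolerance.
Writes per-peptide ladders under results/fragments/ and the parent-ion
match table to results/parent_ion_matches.tsv.
"""

from pathlib import Path

from latamp import STUDY_PEPTIDES, study_peptide
from latamp.fragments import PeakList, by_series, match_peaks, peptide_mass, write_fragment_table

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: Observed singly protonated parental ions from the MALDI spectra (m/z).
OBSERVED_PARENT_IONS = {
    "Ltc-3a": 2483.283,
    "Lt-MAP1": 1574.707,
    "Lt-MAP2": 1629.962,
    "Lt-MAP3": 1488.123,
}


def main() -> None:
    frag_dir = RESULTS / "fragments"
    frag_dir.mkdir(parents=True, exist_ok=True)

    with open(RESULTS / "parent_ion_matches.tsv", "w") as fh:
        fh.write("peptide\tM_avg\tM_mono\tMH_plus_theory\tMH_plus_observed\t"
                 "delta_Da\tmatched\n")
        for name in STUDY_PEPTIDES:
            p = study_peptide(name)
            m = peptide_mass(p)
            series = by_series(p)
            with open(frag_dir / f"{name}.tsv", "w") as lf:
                write_fragment_table(series, lf)

            observed = OBSERVED_PARENT_IONS[name]
            report = match_peaks(series, PeakList((observed,), tolerance=0.5))
            delta = observed - m.MH_plus
            fh.write(f"{name}\t{m.M_avg:.2f}\t{m.M_mono:.3f}\t{m.MH_plus:.3f}\t"
                     f"{observed:.3f}\t{delta:+.3f}\t{report.parent_matched}\n")
            print(f"{name:8s} M_avg={m.M_avg:8.2f}  [M+H]+ theory={m.MH_plus:9.3f}  "
                  f"observed={observed:9.3f}  delta={delta:+.3f} Da  "
                  f"matched={report.parent_matched}")

    print(f"\nwrote ladders under {frag_dir} and "
          f"{RESULTS / 'parent_ion_matches.tsv'}")


if __name__ == "__main__":
    main()
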