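#!/usr/bin/env python
"""Descriptor table for the parent peptide and its three designed analogs.

Computes net charge, mean hydrophobicity, hydrophobic percentage,
hydrophobic moment (Fauchère–Pliška, 100°/residue), and theoretical
masses for latarcin-3a, its helix core (positions 5–17), and the three
Lt-MAP analogs; writes results/descriptors.tsv and the Lt-MAP3 helical
wheel geometry to results/wheel_ltmap3.json.
"""

import json
from pathlib import Path

from latamp import PARENT_REGION, STUDY_PEPTIDES, study_peptide
from latamp.descriptors import INCLUDE_TERMINI, describe, net_charge, wheel_projection
from latamp.design import extract_region
from latamp.fragments import peptide_mass
from latamp.peptides import write_descriptor_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    peptides = [study_peptide(n) for n in STUDY_PEPTIDES]
    fragment = extract_region(peptides[0], *PARENT_REGION)

    rows = []
    for p in peptides + [fragment]:
        d, m = describe(p), peptide_mass(p)
        rows.append({
            "name": p.name, "sequence": p.residues, "length": len(p),
            "Z": d.Z, "H": d.H, "H_pct": d.H_pct, "muH": d.muH,
            "M_avg": round(m.M_avg, 2), "M_mono": round(m.M_mono, 3),
            "MH_plus": round(m.MH_plus, 3),
        })
        print(f"{p.name:14s} {p.residues:22s} Z={d.Z:+d}  H={d.H:.3f}  "
              f"H%={d.H_pct}  muH={d.muH:.3f}  M_avg={m.M_avg:.1f}")

    parent = peptides[0]
    print(f"\nparent Z with the N-terminus counted: "
          f"{net_charge(parent, INCLUDE_TERMINI):+d} "
          f"(side chains only: {net_charge(parent):+d})")

    with open(RESULTS / "descriptors.tsv", "w") as fh:
        write_descriptor_table(rows, fh)

    # wheel geometry of the most cationic analog: all four leucines should
    # sit on the hydrophobic face
    map3 = study_peptide("Lt-MAP3")
    w = wheel_projection(map3)
    leu_in_face = [e.index for e in w.entries
                   if e.residue == "L" and w.in_face(e.index)]
    print(f"\nLt-MAP3 wheel: moment direction {w.moment_angle:.1f} deg, "
          f"leucines on hydrophobic face at positions {leu_in_face}")
    with open(RESULTS / "wheel_ltmap3.json", "w") as fh:
        json.dump({
            "delta": w.delta, "moment_angle": round(w.moment_angle, 2),
            "face_arc": [round(a, 2) for a in w.face_arc],
            "residues": [
                {"index": e.index, "residue": e.residue,
                 "angle": round(e.angle, 1), "hydrophobic": e.hydrophobic,
                 "in_face": w.in_face(e.index)}
                for e in w.entries
            ],
        }, fh, indent=2)
    print(f"\nwrote {RESULTS / 'descriptors.tsv'} and "
          f"{RESULTS / 'wheel_ltmap3.json'}")


if __name__ == "__main__":
    main()
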