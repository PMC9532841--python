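"""latamp: rational design and assay reduction for latarcin-3a-derived
amphipathic helical antimicrobial peptides.

The library covers the full desk pipeline of a first-generation analog
study: physicochemical descriptors (net charge, hydrophobicity,
hydrophobic moment, helical wheel), constrained analog enumeration on the
parent helix region, theoretical mass and b/y fragment verification, and
reduction of microdilution / biofilm / hemolysis / viability plate data
to MIC, MBIC, hemolysis %, and EC50 endpoints.
"""

from .peptides import PeptideSequence, parse_fasta, validate_sequence

__version__ = "0.1.0"

#: The study peptides: the latarcin-3a parent, its helical core region
#: (parent positions 5-17), and the three designed analogs.
STUDY_PEPTIDES = {
    "Ltc-3a": "SWKSMAKKLKEYMEKLKQRA",
    "Lt-MAP1": "LAKKLKEYLEKLV",
    "Lt-MAP2": "LIKKLKEYLKKLI",
    "Lt-MAP3": "LAKKLAKYLKKAL",
}

PARENT_REGION = (5, 17)  # 1-based inclusive coordinates of the helix core
PARENT_FRAGMENT = "MAKKLKEYMEKLK"


def study_peptide(name: str) -> PeptideSequence:
    """One of the named study peptides as a validated sequence."""
    return validate_sequence(STUDY_PEPTIDES[name], name=name)


__all__ = [
    "PeptideSequence",
    "parse_fasta",
    "validate_sequence",
    "STUDY_PEPTIDES",
    "PARENT_REGION",
    "PARENT_FRAGMENT",
    "study_peptide",
    "__version__",
]
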