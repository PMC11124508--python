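"""Regenerate the bundled default hydropathic parameter dictionary.

Atom names and connectivity for the 20 standard amino acids are taken
from the Chemical Component Dictionary templates bundled with biotite;
hydrophobic constants come from simple atomic-contribution rules
(documented in docs/methods.md) in the spirit of Ghose-Crippen atomic
LogP schemes.  Run from the repository root:

    python scripts/build_default_dictionary.py
"""

from pathlib import Path

import biotite.structure.info as info

from hintmd.params import (
    ParameterDictionary,
    ParameterEntry,
    VDW_RADII,
    write_parameter_dictionary,
)

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

AROMATIC_CARBONS = {
    "HIS": {"CG", "CD2", "CE1"},
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
}
# carbons of carboxylate / amide / guanidinium groups: polar carbons
POLAR_CARBONS = {
    "ASP": {"CG"}, "GLU": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"}, "ARG": {"CZ"},
}
METHYL_CARBONS = {
    "ALA": {"CB"}, "VAL": {"CG1", "CG2"}, "LEU": {"CD1", "CD2"},
    "ILE": {"CG2", "CD1"}, "THR": {"CG2"}, "MET": {"CE"},
}


def carbon_entry(res: str, name: str) -> ParameterEntry:
    if name == "C" or name in POLAR_CARBONS.get(res, ()):
        return ParameterEntry(-0.25, "polar_neutral", VDW_RADII["C"])
    if name in AROMATIC_CARBONS.get(res, ()):
        return ParameterEntry(+0.30, "hydrophobic", VDW_RADII["C"])
    if name == "CA":
        return ParameterEntry(+0.15, "hydrophobic", VDW_RADII["C"])
    if name in METHYL_CARBONS.get(res, ()):
        return ParameterEntry(+0.65, "hydrophobic", VDW_RADII["C"])
    return ParameterEntry(+0.45, "hydrophobic", VDW_RADII["C"])


def nitrogen_entry(res: str, name: str) -> ParameterEntry:
    r = VDW_RADII["N"]
    if res == "LYS" and name == "NZ":
        return ParameterEntry(-1.20, "base", r)  # protonated amine at pH 7
    if res == "ARG" and name in ("NE", "NH1", "NH2"):
        return ParameterEntry(-1.00, "base", r)  # guanidinium, protonated
    if res == "HIS" and name in ("ND1", "NE2"):
        return ParameterEntry(-0.60, "polar_neutral", r)  # neutral imidazole
    if res == "TRP" and name == "NE1":
        return ParameterEntry(-0.40, "base", r)  # indole NH, donor only
    if (res, name) in (("ASN", "ND2"), ("GLN", "NE2")):
        return ParameterEntry(-0.55, "base", r)  # amide NH2, donor
    return ParameterEntry(-0.60, "base", r)  # backbone amide N


def oxygen_entry(res: str, name: str) -> ParameterEntry:
    r = VDW_RADII["O"]
    if name == "OXT":
        return ParameterEntry(-1.00, "acid", r)  # C-terminal carboxylate
    if (res in ("ASP",) and name in ("OD1", "OD2")) or (
        res in ("GLU",) and name in ("OE1", "OE2")
    ):
        return ParameterEntry(-1.00, "acid", r)  # deprotonated at pH 7
    if (res, name) in (("ASN", "OD1"), ("GLN", "OE1")):
        return ParameterEntry(-0.60, "acid", r)  # amide carbonyl, acceptor
    if (res, name) in (("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")):
        return ParameterEntry(-0.55, "polar_neutral", r)  # hydroxyl: donor+acceptor
    return ParameterEntry(-0.75, "acid", r)  # backbone carbonyl O, acceptor


def sulfur_entry(res: str, name: str) -> ParameterEntry:
    r = VDW_RADII["S"]
    if res == "CYS" and name == "SG":
        return ParameterEntry(-0.30, "polar_neutral", r)
    return ParameterEntry(-0.25, "polar_neutral", r)  # MET thioether


def build() -> ParameterDictionary:
    entries: dict[tuple[str, str], ParameterEntry] = {}
    for res in AMINO_ACIDS:
        template = info.residue(res)
        elements = {n: e for n, e in zip(template.atom_name, template.element)}
        bonds = template.bonds.as_array()[:, :2]
        neighbor = {}
        for i, j in bonds:
            neighbor.setdefault(template.atom_name[i], []).append(template.atom_name[j])
            neighbor.setdefault(template.atom_name[j], []).append(template.atom_name[i])
        for name, elem in elements.items():
            if elem == "H":
                heavies = [n for n in neighbor.get(name, []) if elements[n] != "H"]
                heavy_elem = elements[heavies[0]] if heavies else "C"
                if heavy_elem in ("N", "O", "S"):
                    entries[(res, name)] = ParameterEntry(-0.20, "base", VDW_RADII["H"])
                else:
                    entries[(res, name)] = ParameterEntry(+0.10, "hydrophobic", VDW_RADII["H"])
            elif elem == "C":
                entries[(res, name)] = carbon_entry(res, name)
            elif elem == "N":
                entries[(res, name)] = nitrogen_entry(res, name)
            elif elem == "O":
                entries[(res, name)] = oxygen_entry(res, name)
            elif elem == "S":
                entries[(res, name)] = sulfur_entry(res, name)
        # N-terminal ammonium hydrogens
        for h in ("H1", "H2", "H3"):
            entries[(res, h)] = ParameterEntry(-0.20, "base", VDW_RADII["H"])
    d = ParameterDictionary(
        entries=entries,
        provenance=(
            "rule-based atomic LogP contributions (Ghose-Crippen-style), "
            "neutral-pH protonation; see docs/methods.md"
        ),
        version="1.0",
    )
    d.validate()
    return d


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "hintmd" / "data" / "default_dictionary.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    write_parameter_dictionary(build(), out)
    print(f"wrote {out}")
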