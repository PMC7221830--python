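"""Editable chemistry tables: vdW radii, feature patterns, atom classes.

These tables are deliberately plain data so that a user can adapt feature
perception or descriptor classes without touching algorithm code.  The
feature definitions mirror the six classical pharmacophore feature kinds —
hydrogen-bond acceptor (A), hydrogen-bond donor (D), hydrophobic (H),
negative (N), positive (P) and aromatic ring (R) — using SMARTS where a
substructure suffices and dedicated perception code for rings and
hydrophobic clusters.
"""

from __future__ import annotations

# Bondi van der Waals radii (Angstrom); frozen so occupancy descriptors are
# bit-stable across releases.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}
DEFAULT_VDW = 1.70

# Hydrogen-bond acceptor SMARTS: each pattern tags the acceptor heavy atom
# (first atom of the match).
ACCEPTOR_SMARTS: tuple[str, ...] = (
    "[OX1]=[#6]",            # carbonyl / carboxylate oxygen
    "[OX1-]",                # anionic oxygen
    "[OX2;!$(O=*)]([#6])[#6,#1]",  # ether / hydroxyl oxygen
    "[nX2;+0]",              # pyridine-type aromatic nitrogen
    "[NX1]#[#6]",            # nitrile nitrogen
    "[NX3;+0;!$(N=*);!$(N-a);!$(N-[#6]=[O,S,N]);!$(n)]",  # sp3 amine lone pair
)

# Hydrogen-bond donor SMARTS: heavy atoms bearing at least one proton.
DONOR_SMARTS: tuple[str, ...] = (
    "[#7;H1,H2,H3]",
    "[#8;H1,H2]",
    "[#16;H1]",
)

# Atom classes used by the occupancy-grid QSAR descriptor.  Order is the
# canonical descriptor layout.
ATOM_CLASSES: tuple[str, ...] = ("D", "H", "N", "P", "W", "X")


def vdw_radius(symbol: str) -> float:
    return VDW_RADII.get(symbol, DEFAULT_VDW)


def classify_atom(atom) -> str:
    """Assign a heavy atom to one of the QSAR descriptor classes.

    D: donor-hydrogen carriers (N/O/S with >=1 H); N/P: formally charged;
    W: acceptor or electron-withdrawing heteroatoms and carbonyl-like
    carbons; H: hydrophobic carbon; X: anything else.
    """
    z = atom.GetAtomicNum()
    chg = atom.GetFormalCharge()
    if chg < 0:
        return "N"
    if chg > 0:
        return "P"
    if z in (7, 8, 16) and atom.GetTotalNumHs() >= 1:
        return "D"
    if z in (7, 8, 9, 17, 35, 53):
        return "W"
    if z == 6:
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom)
            if other.GetAtomicNum() in (7, 8, 16) and bond.GetBondTypeAsDouble() > 1.0:
                return "W"
        return "H"
    return "X"
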