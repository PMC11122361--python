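"""Independent atomic-composition oracle for PMAA nominal masses.

Builds each derivative atom by atom (backbone CH/CH2 units plus
explicit OMe/OAc substituent groups), deliberately not sharing the
implementation's increment-from-alditol route.
"""

from collections import Counter

SUGAR_SHAPE = {
    # sugar -> (backbone carbons, oxygen-bearing carbons)
    "Gal": (6, {1, 2, 3, 4, 5, 6}),
    "Glc": (6, {1, 2, 3, 4, 5, 6}),
    "Man": (6, {1, 2, 3, 4, 5, 6}),
    "Xyl": (5, {1, 2, 3, 4, 5}),
    "Ara": (5, {1, 2, 3, 4, 5}),
    "Rha": (6, {1, 2, 3, 4, 5}),
    "Fuc": (6, {1, 2, 3, 4, 5}),
}


def oracle_mass(sugar, acetyl, methyl, bridged, deuterated):
    n, oxygens = SUGAR_SHAPE[sugar]
    atoms = Counter()
    for c in range(1, n + 1):
        atoms["C"] += 1
        if c in (1, n):
            atoms["H"] += 2 if c in oxygens else 3
        else:
            atoms["H"] += 1
    for _ in acetyl:   # -O-C(=O)-CH3
        atoms.update({"O": 2, "C": 2, "H": 3})
    for _ in methyl:   # -O-CH3
        atoms.update({"O": 1, "C": 1, "H": 3})
    if bridged:        # one bridging ether oxygen
        atoms["O"] += 1
    if deuterated:
        atoms["H"] -= 1
        atoms["D"] += 1
    return 12 * atoms["C"] + atoms["H"] + 16 * atoms["O"] + 2 * atoms["D"]
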