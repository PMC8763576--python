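"""FXI-specific reference data: domain boundaries, disulfide topology,
functional sites and the bundled protein sequence.

All residue numbers are HGVS protein numbering (Met1 at the start of the
18-residue signal peptide; mature protein starts at Glu19). The four
Apple (Ap) domains each carry six conserved cysteines (C1..C6) forming
three intradomain bridges C1-C6, C2-C5, C3-C4; the serine protease (SP)
domain carries five more bridges, and Cys339 of Ap4 forms the interchain
bridge that stabilises the circulating dimer.
"""

from __future__ import annotations

from importlib import resources

from .census import DomainMap

#: Default domain boundaries, bracketing the printed disulfide spans and
#: the Arg387-Ile388 activation site. Configurable; analyses depending on
#: the Ap4/SP split are robust to placements in [375, 415].
FXI_DOMAIN_MAP = DomainMap(
    intervals=(
        ("signal", 1, 18),
        ("Ap1", 19, 108),
        ("Ap2", 109, 198),
        ("Ap3", 199, 288),
        ("Ap4", 289, 379),
        ("SP", 380, 625),
    )
)

APPLE_DOMAINS = ("Ap1", "Ap2", "Ap3", "Ap4")

#: Six conserved Cys per Apple domain, in sequence order (C1..C6).
AP_CYS_ANCHORS: dict[str, tuple[int, ...]] = {
    "Ap1": (20, 46, 50, 56, 76, 103),
    "Ap2": (110, 136, 140, 146, 165, 193),
    "Ap3": (200, 226, 230, 236, 255, 283),
    "Ap4": (291, 317, 321, 327, 346, 374),
}

#: The 17 disulfide bridges of one FXI monomer: three per Apple domain
#: (C1-C6, C2-C5, C3-C4) plus five in the SP domain.
FXI_DISULFIDES: tuple[tuple[int, int], ...] = (
    # Ap1
    (20, 103), (46, 76), (50, 56),
    # Ap2
    (110, 193), (136, 165), (140, 146),
    # Ap3
    (200, 283), (226, 255), (230, 236),
    # Ap4
    (291, 374), (317, 346), (321, 327),
    # SP
    (380, 500), (416, 432), (514, 581), (545, 560), (571, 599),
)

#: Unpaired cysteine in Ap1.
FXI_FREE_CYS = 29

#: Interchain bridge between the two Ap4 domains of the dimer.
FXI_INTERCHAIN_DISULFIDE = (339, 339)

#: SP-domain catalytic triad (legacy His413-Asp462-Ser557).
CATALYTIC_TRIAD = (431, 480, 575)

#: Activation cleavage site.
ACTIVATION_SITE = (387, 388)

#: The 17 Ap4 residues at the dimer interface (buried surface area > 5 A^2):
#: the Leu302-Val309 stretch plus nine further contacts.
DIMER_INTERFACE_RESIDUES: tuple[int, ...] = tuple(range(302, 310)) + (
    333, 339, 340, 345, 347, 349, 357, 360, 363,
)

#: Interchain salt bridges stabilising the dimer.
DIMER_SALT_BRIDGES: tuple[tuple[int, int], ...] = ((305, 349), (307, 363))


def load_fxi_sequence() -> str:
    """Return the bundled 625-residue FXI sequence (one-letter codes).

    The bundled FASTA is a synthetic stand-in, not the database reference
    sequence: every residue identity that the analyses depend on
    (conserved Cys topology, catalytic triad, activation site, named
    variant and interface positions) is fixed; remaining positions are
    deterministic filler. See the file header and docs/methods.md.
    """
    path = resources.files("fxivar.data").joinpath("fxi_sequence_synthetic.fasta")
    lines = path.read_text().splitlines()
    seq = "".join(line.strip() for line in lines if not line.startswith(">"))
    return seq


def apple_sequences(sequence: str | None = None) -> dict[str, str]:
    """Extract the four Apple-domain sequences from the full sequence."""
    seq = sequence or load_fxi_sequence()
    out = {}
    for name in APPLE_DOMAINS:
        start, end = FXI_DOMAIN_MAP.span(name)
        out[name] = seq[start - 1 : end]
    return out


def bundled_census_path():
    """Path to the bundled census fixture transcribed from printed tallies."""
    return resources.files("fxivar.data").joinpath("fxi_census.csv")
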