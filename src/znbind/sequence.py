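"""Canonical human alpha-synuclein sequence and average-mass helpers.

The package works with N-terminally acetylated alpha-synuclein (140
residues) throughout, and all m/z arithmetic uses average (not
monoisotopic) masses: native spectra of a 14.5 kDa protein on a
TWIMS-class instrument resolve metal-adduct envelopes, not isotopes.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

#: Human alpha-synuclein, UniProt P37840, 140 residues.
ALPHA_SYNUCLEIN_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYV"
    "GSKTKEGVVHGVATVAEKTKEQVTNVGGAVVTGVTAVAQK"
    "TVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
    "DNEAYEMPSEEGYQDYEPEA"
)

#: Average mass of the N-terminal acetyl modification (C2H2O), Da.
ACETYL_MASS = 42.0367

#: Average proton mass used for positive-mode m/z arithmetic, Da.
PROTON_MASS = 1.00728


def average_mass(sequence: str = ALPHA_SYNUCLEIN_SEQUENCE,
                 n_terminal_acetyl: bool = True) -> float:
    """Average molecular mass (Da) of a peptide sequence.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence.
    n_terminal_acetyl : bool
        Add the average mass of an N-terminal acetyl group.
    """
    m = _pmass.calculate_mass(sequence=sequence, average=True)
    if n_terminal_acetyl:
        m += ACETYL_MASS
    return m
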