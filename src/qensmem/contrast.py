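"""Incoherent-scattering contrast and helical-peptide sequence descriptors.

Incoherent neutron scattering is dominated by hydrogen (sigma_inc = 80.27 b
vs 2.05 b for deuterium), so the spectral weight of a membrane component is
well approximated by its cross-section-weighted H/D count.  Selective chain
deuteration of the lipid (DMPC-d54: the 54 acyl-chain hydrogens exchanged for
deuterium) raises the peptide's share of the signal from roughly one fifth to
roughly one half at 6 mol% peptide, which is what makes the peptide dynamics
experimentally accessible.

Sequence descriptors follow the HELIQUEST conventions: net charge from
K/R/D/E counts, mean hydrophobicity on the Fauchere-Pliska scale, and the
Eisenberg hydrophobic moment for an ideal alpha helix (100 deg per residue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SIGMA_INC_D, SIGMA_INC_H

__all__ = [
    "PeptideSequence",
    "MoleculeComposition",
    "DMPC",
    "DMPC_D54",
    "TFRC_ORIGINAL",
    "TFRC_MODIFIED",
    "peptide_hydrogens",
    "peptide_composition",
    "scattering_fraction",
    "net_charge",
    "mean_hydrophobicity",
    "hydrophobic_moment",
]

#: Covalent hydrogens per residue in peptide-bond form (amino acid minus H2O).
RESIDUE_H: dict[str, int] = {
    "A": 5, "R": 12, "N": 6, "D": 5, "C": 5, "Q": 8, "E": 7, "G": 3, "H": 7,
    "I": 11, "L": 11, "K": 12, "M": 9, "F": 9, "P": 7, "S": 5, "T": 7,
    "W": 10, "Y": 9, "V": 9,
}

#: Exchangeable (labile) hydrogens per residue: the backbone amide H (absent
#: for proline) plus labile side-chain hydrogens, for the optional
#: H/D-exchange convention in D2O buffer.
RESIDUE_EXCHANGEABLE_H: dict[str, int] = {
    "A": 1, "R": 6, "N": 3, "D": 1, "C": 2, "Q": 3, "E": 1, "G": 1, "H": 2,
    "I": 1, "L": 1, "K": 4, "M": 1, "F": 1, "P": 0, "S": 2, "T": 2,
    "W": 2, "Y": 2, "V": 1,
}

#: Fauchere-Pliska hydrophobicity scale as used by HELIQUEST.
FAUCHERE_PLISKA: dict[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54, "Q": -0.22,
    "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80, "L": 1.70, "K": -0.99,
    "M": 1.23, "F": 1.79, "P": 0.72, "S": -0.04, "T": 0.26, "W": 2.25,
    "Y": 0.96, "V": 1.22,
}

#: Transferrin-receptor transmembrane sequences: the native stretch and the
#: solubility-modified variant used in the scattering experiments.
TFRC_ORIGINAL = "KPKRCSGSICYGTIAVIVFFLIGFMIGYLGYCKGVEPKTE"
TFRC_MODIFIED = "NKKPKRSYGTIAVIVFFLIGFMIGYLGYSKTESEK"


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter amino-acid sequence restricted to the canonical 20."""

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must not be empty")
        bad = set(self.residues) - set(RESIDUE_H)
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


def _as_sequence(seq: "PeptideSequence | str") -> PeptideSequence:
    return seq if isinstance(seq, PeptideSequence) else PeptideSequence(seq)


@dataclass(frozen=True)
class MoleculeComposition:
    """Covalently bound hydrogen and deuterium counts of one molecule."""

    n_H: int
    n_D: int = 0

    def __post_init__(self) -> None:
        if self.n_H < 0 or self.n_D < 0:
            raise ValueError("H/D counts must be non-negative")

    @property
    def incoherent_weight(self) -> float:
        """Cross-section-weighted count, barn (non-H/D atoms neglected)."""
        return self.n_H * SIGMA_INC_H + self.n_D * SIGMA_INC_D


#: Protonated DMPC: 72 covalent hydrogens.
DMPC = MoleculeComposition(n_H=72, n_D=0)
#: Chain-deuterated DMPC-d54: 18 remaining hydrogens, 54 chain deuteriums.
DMPC_D54 = MoleculeComposition(n_H=18, n_D=54)


def peptide_hydrogens(seq: "PeptideSequence | str") -> int:
    """Covalent hydrogen count: per-residue formulas plus 2 terminal H."""
    s = _as_sequence(seq)
    return sum(RESIDUE_H[r] for r in s.residues) + 2


def peptide_composition(
    seq: "PeptideSequence | str", exchange: bool = False
) -> MoleculeComposition:
    """Peptide H/D composition.

    With ``exchange=True`` the labile hydrogens (backbone amides and labile
    side-chain H, plus the two terminal H) are counted as deuterium, as after
    full exchange with D2O buffer.  The default (no exchange) reproduces the
    all-hydrogen convention.
    """
    s = _as_sequence(seq)
    total = peptide_hydrogens(s)
    if not exchange:
        return MoleculeComposition(n_H=total, n_D=0)
    labile = sum(RESIDUE_EXCHANGEABLE_H[r] for r in s.residues) + 2
    return MoleculeComposition(n_H=total - labile, n_D=labile)


def scattering_fraction(
    peptide: MoleculeComposition,
    lipid: MoleculeComposition,
    lipids_per_peptide: float,
) -> float:
    """Peptide share of the total incoherent scattering.

    ``p = W_pep / (W_pep + N * W_lip)`` with W the cross-section-weighted
    H/D count of one molecule and N the number of lipids per peptide.
    """
    if lipids_per_peptide < 0:
        raise ValueError("lipids_per_peptide must be non-negative")
    w_pep = peptide.incoherent_weight
    w_lip = lipid.incoherent_weight
    total = w_pep + lipids_per_peptide * w_lip
    if total == 0.0:
        raise ValueError("total scattering weight is zero")
    return w_pep / total


def net_charge(seq: "PeptideSequence | str") -> int:
    """Net charge at neutral pH: (#K + #R) - (#D + #E); His neutral,
    termini ignored."""
    s = _as_sequence(seq).residues
    return sum(s.count(r) for r in "KR") - sum(s.count(r) for r in "DE")


def mean_hydrophobicity(seq: "PeptideSequence | str") -> float:
    """Arithmetic mean of Fauchere-Pliska residue hydrophobicities."""
    s = _as_sequence(seq).residues
    return sum(FAUCHERE_PLISKA[r] for r in s) / len(s)


def hydrophobic_moment(seq: "PeptideSequence | str", delta_deg: float = 100.0) -> float:
    """Eisenberg hydrophobic moment per residue for an ideal helix.

    ``mu_H = |sum_i H_i (cos(i*delta), sin(i*delta))| / N`` with delta the
    helical twist per residue (100 deg for an alpha helix).
    """
    s = _as_sequence(seq).residues
    h = np.array([FAUCHERE_PLISKA[r] for r in s])
    angles = np.deg2rad(delta_deg) * np.arange(len(s))
    vec = np.array([np.sum(h * np.cos(angles)), np.sum(h * np.sin(angles))])
    return float(np.hypot(*vec)) / len(s)
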