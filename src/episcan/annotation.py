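"""Per-residue annotation: conservation, relative accessibility, exposure.

The conservation score of a residue is the Kullback-Leibler-style divergence
of its evolutionary-profile column from a background amino-acid distribution::

    CON = sum_{i=1..20} P_i * log2(P_i / P_ib)

where ``P_i`` is the residue's Weighted Observation Percentage divided by 100
and ``P_ib`` the background probability of amino acid ``i``. WOP rows are used
as-is (divided by 100, not renormalized to sum to 1). Rows whose 20 entries
are all zero are replaced, before scoring, by the average WOP vector of
non-zero rows of the same residue type in the training set.

Accessibility: raw per-residue ASA (Å²) is normalized by the residue's
extended Ala-X-Ala tripeptide reference area to a relative solvent
accessibility (RSA) in [0, 1]; residues are called buried when RSA < 0.25 and
solvent-exposed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (AA_ALPHABET, FormatError, RawChain, SsRsaTable,
                         WopMatrix)

#: Exposure threshold: buried iff RSA < this fraction.
EXPOSURE_THRESHOLD = 0.25

#: Robinson-Robinson amino-acid background frequencies (normalized on load).
ROBINSON_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

#: Extended Ala-X-Ala tripeptide reference ASA (Å²) for RSA normalization.
ALA_X_ALA_AREA = {
    "A": 110.2, "C": 140.4, "D": 144.1, "E": 174.7, "F": 200.7,
    "G": 78.7, "H": 181.9, "I": 185.0, "K": 205.7, "L": 183.1,
    "M": 200.1, "N": 146.4, "P": 141.9, "Q": 178.6, "R": 229.0,
    "S": 117.2, "T": 138.7, "V": 153.7, "W": 240.5, "Y": 213.7,
}


@dataclass(frozen=True)
class BackgroundFreqs:
    """Background amino-acid probabilities, as a 20-vector in alphabet order."""

    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.p.shape != (20,):
            raise ValueError("background must have exactly 20 entries")
        if (self.p <= 0).any():
            raise ValueError("background probabilities must be positive")
        if abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"background probabilities sum to {self.p.sum():.8f}, not 1")

    @classmethod
    def from_mapping(cls, table: dict[str, float],
                     normalize: bool = True) -> "BackgroundFreqs":
        missing = [aa for aa in AA_ALPHABET if aa not in table]
        if missing:
            raise ValueError(f"background table missing residues {missing}")
        p = np.array([float(table[aa]) for aa in AA_ALPHABET])
        if normalize:
            p = p / p.sum()
        return cls(p)

    @classmethod
    def robinson_robinson(cls) -> "BackgroundFreqs":
        return cls.from_mapping(ROBINSON_ROBINSON)

    @classmethod
    def uniform(cls) -> "BackgroundFreqs":
        return cls(np.full(20, 0.05))


@dataclass
class AnnotatedChain:
    """A chain plus aligned per-residue SS, RSA, exposure and conservation."""

    chain: RawChain
    ss: str
    rsa: np.ndarray
    exposure: np.ndarray  # bool, True = exposed
    conservation: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.chain)
        for name in ("ss", "rsa", "exposure", "conservation"):
            if len(getattr(self, name)) != L:
                raise FormatError(
                    f"channel {name!r} has length {len(getattr(self, name))},"
                    f" expected {L} for chain {self.chain.id!r}")
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=bool)
        self.conservation = np.asarray(self.conservation, dtype=float)

    def __len__(self) -> int:
        return len(self.chain)


def conservation_score(wop_row: np.ndarray,
                       background: BackgroundFreqs) -> float:
    """KL-style conservation of one profile column against the background.

    ``wop_row`` holds 20 observation percentages (0-100 scale); zero entries
    contribute nothing (the 0*log(0) convention).
    """
    row = np.asarray(wop_row, dtype=float)
    if row.shape != (20,):
        raise ValueError("WOP row must have 20 entries")
    if (row < 0).any():
        raise ValueError("negative WOP entry")
    p = row / 100.0
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / background.p[mask])))


def conservation_profile(wop: WopMatrix, background: BackgroundFreqs,
                         ) -> np.ndarray:
    """Conservation score for every residue; zero rows must be resolved first."""
    if wop.zero_rows.any():
        raise ValueError(
            "WOP matrix still has all-zero rows; apply wop_fallback first")
    return np.array([conservation_score(r, background) for r in wop.values])


def build_wop_fallback_table(matrices: list[WopMatrix],
                             sequences: list[str]) -> dict[str, np.ndarray]:
    """Average WOP vector per residue type over non-zero rows of a training set.

    Residue types with no non-zero row anywhere get the uniform 5% vector so
    the table is total over the alphabet.
    """
    sums: dict[str, np.ndarray] = {aa: np.zeros(20) for aa in AA_ALPHABET}
    counts: dict[str, int] = {aa: 0 for aa in AA_ALPHABET}
    for wop, seq in zip(matrices, sequences):
        if len(wop) != len(seq):
            raise FormatError("WOP/sequence length mismatch in fallback build")
        for aa, row, is_zero in zip(seq, wop.values, wop.zero_rows):
            if not is_zero:
                sums[aa] += row
                counts[aa] += 1
    table: dict[str, np.ndarray] = {}
    for aa in AA_ALPHABET:
        if counts[aa]:
            table[aa] = sums[aa] / counts[aa]
        else:
            table[aa] = np.full(20, 5.0)
    return table


def wop_fallback(wop: WopMatrix, sequence: str,
                 fallback_table: dict[str, np.ndarray]) -> WopMatrix:
    """Replace all-zero WOP rows by the fallback vector of the residue type."""
    if len(wop) != len(sequence):
        raise FormatError(
            f"WOP length {len(wop)} does not match sequence length "
            f"{len(sequence)}")
    if not wop.zero_rows.any():
        return wop
    values = wop.values.copy()
    for i in np.flatnonzero(wop.zero_rows):
        aa = sequence[i]
        if aa not in fallback_table:
            raise KeyError(
                f"residue type {aa!r} absent from WOP fallback table")
        values[i] = fallback_table[aa]
    return WopMatrix(values)


def normalize_rsa(asa: float, residue: str,
                  reference: dict[str, float] | None = None) -> float:
    """ASA (Å²) -> relative accessibility in [0, 1], clipped at 1."""
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    ref = (reference or ALA_X_ALA_AREA)
    if residue not in ref:
        raise KeyError(f"no reference area for residue {residue!r}")
    return min(asa / ref[residue], 1.0)


def exposure_call(rsa: float, threshold: float = EXPOSURE_THRESHOLD) -> bool:
    """True = solvent exposed (RSA >= threshold), False = buried."""
    if not 0 <= rsa <= 1:
        raise ValueError(f"RSA must lie in [0, 1], got {rsa}")
    return rsa >= threshold


def annotate_chain(chain: RawChain, ss_rsa: SsRsaTable, wop: WopMatrix,
                   background: BackgroundFreqs,
                   fallback_table: dict[str, np.ndarray],
                   reference_areas: dict[str, float] | None = None,
                   exposure_threshold: float = EXPOSURE_THRESHOLD,
                   ) -> AnnotatedChain:
    """Assemble all per-residue channels for one chain."""
    L = len(chain)
    if len(ss_rsa) != L:
        raise FormatError(
            f"SS/RSA channel length {len(ss_rsa)} does not match chain "
            f"{chain.id!r} length {L}")
    if len(wop) != L:
        raise FormatError(
            f"WOP channel length {len(wop)} does not match chain "
            f"{chain.id!r} length {L}")
    if ss_rsa.is_asa:
        rsa = np.array([normalize_rsa(v, aa, reference_areas)
                        for v, aa in zip(ss_rsa.values, chain.sequence)])
    else:
        rsa = np.clip(ss_rsa.values, 0.0, 1.0)
    exposure = rsa >= exposure_threshold
    resolved = wop_fallback(wop, chain.sequence, fallback_table)
    cons = conservation_profile(resolved, background)
    return AnnotatedChain(chain=chain, ss=ss_rsa.ss, rsa=rsa,
                         exposure=exposure, conservation=cons)
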