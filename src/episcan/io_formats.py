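"""Readers and writers for every external representation the pipeline touches.

Formats handled here:

* FASTA antigen chains (via Biopython).
* PSI-BLAST ASCII profiles (the classic ``-Q`` layout) or plain 20-column TSV,
  yielding the per-residue Weighted Observation Percentage (WOP) matrix.
* Per-residue secondary-structure / solvent-accessibility tables (TSV).
* 400-entry dipeptide antigenicity scales (3-column TSV).
* Labeled 20-mer fragment datasets (one ``PEPTIDE label`` line per record).
* Per-residue propensity profiles (TSV) and model-bundle serialization.

All user-facing coordinates are 1-based inclusive. Amino-acid vector columns
are kept in alphabetical one-letter order internally (``AA_ALPHABET``);
PSI-BLAST's native column order is translated on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical internal column order for 20-vectors.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Column order used by PSI-BLAST ASCII profile output.
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity codes tolerated in lenient mode.
AMBIGUOUS_RESIDUES = "XBZUJO"

#: Secondary-structure alphabet: helix, strand, coil.
SS_CLASSES = "HEC"

_PSIBLAST_TO_ALPHA = [PSIBLAST_AA_ORDER.index(aa) for aa in AA_ALPHABET]

EPITOPE_LABELS = {"1", "e", "epitope", "pos", "positive", "true"}
NON_EPITOPE_LABELS = {"0", "n", "ne", "non-epitope", "nonepitope", "neg",
                      "negative", "false"}


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawChain:
    """An antigen chain: identifier plus amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"chain {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class WopMatrix:
    """Per-residue WOP percentages (0-100), columns in ``AA_ALPHABET`` order.

    ``zero_rows[i]`` flags residues whose 20 observation percentages are all
    zero; those rows must be replaced by a residue-type fallback vector before
    conservation scoring.
    """

    values: np.ndarray  # (L, 20) float
    zero_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise FormatError(
                f"WOP matrix must be L x 20, got shape {self.values.shape}")
        if (self.values < 0).any() or (self.values > 100).any():
            raise FormatError("WOP entries must lie in [0, 100]")
        if self.zero_rows is None:
            self.zero_rows = ~self.values.any(axis=1)
        self.zero_rows = np.asarray(self.zero_rows, dtype=bool)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SsRsaTable:
    """Per-residue secondary structure and solvent accessibility.

    ``is_asa`` marks raw accessible-surface areas in Å² (to be normalized by
    the residue's extended Ala-X-Ala reference area); otherwise values are
    already relative accessibilities in [0, 1].
    """

    ss: str
    values: np.ndarray
    is_asa: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ss) != len(self.values):
            raise FormatError(
                "SS/RSA channel length mismatch: "
                f"{len(self.ss)} SS labels vs {len(self.values)} values")
        bad = sorted(set(self.ss) - set(SS_CLASSES))
        if bad:
            raise FormatError(f"illegal secondary-structure labels: {bad}")
        if (self.values < 0).any():
            raise FormatError("negative accessibility value")

    def __len__(self) -> int:
        return len(self.ss)


@dataclass
class DipeptideScale:
    """Ordered amino-acid-pair propensity scale (400 entries when complete).

    When ``normalized`` is true all values lie strictly inside (-1, 1), the
    convention for renormalized antigenicity scales.
    """

    values: dict[str, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.normalized:
            bad = {k: v for k, v in self.values.items() if not -1 < v < 1}
            if bad:
                raise FormatError(
                    f"normalized scale has values outside (-1, 1): "
                    f"{sorted(bad)[:5]}")

    @property
    def complete(self) -> bool:
        return len(self.values) == 400

    def lookup(self, pair: str, strict: bool = True) -> float:
        try:
            return self.values[pair]
        except KeyError:
            if strict:
                raise FormatError(f"dipeptide {pair!r} missing from scale")
            return 0.0

    def renormalized(self) -> "DipeptideScale":
        """Min-max map the raw values linearly into the open (-1, 1) interval."""
        vals = np.array(list(self.values.values()))
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            mapped = {k: 0.0 for k in self.values}
        else:
            # shrink marginally so the extremes stay strictly inside (-1, 1)
            scale = (1.0 - 1e-9) * 2.0 / (hi - lo)
            mapped = {k: (v - lo) * scale - (1.0 - 1e-9)
                      for k, v in self.values.items()}
        return DipeptideScale(mapped, normalized=True)


@dataclass(frozen=True)
class FragmentRecord:
    """A labeled 20-mer peptide, optionally tagged with its source chain."""

    peptide: str
    label: bool  # True = epitope
    source_id: str | None = None
    offset: int | None = None  # 1-based start in the source chain

    def __post_init__(self) -> None:
        if len(self.peptide) != 20:
            raise FormatError(
                f"fragment peptide must be 20 residues, got "
                f"{len(self.peptide)}: {self.peptide!r}")


# ---------------------------------------------------------------------------
# Sequence validation
# ---------------------------------------------------------------------------

def validate_sequence(seq: str, strict: bool = True,
                      fallback_residue: str = "A") -> str:
    """Uppercase and validate an amino-acid string.

    In strict mode any character outside the 20 canonical residues raises; in
    lenient mode recognized ambiguity codes (X/B/Z/U/J/O) are mapped to
    ``fallback_residue`` and anything else still raises.
    """
    seq = seq.upper()
    out = []
    for i, ch in enumerate(seq):
        if ch in AA_ALPHABET:
            out.append(ch)
        elif not strict and ch in AMBIGUOUS_RESIDUES:
            out.append(fallback_residue)
        else:
            raise FormatError(
                f"illegal residue {ch!r} at position {i + 1}")
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, strict: bool = True,
               fallback_residue: str = "A") -> list[RawChain]:
    """Read antigen chains from a FASTA file, order preserved."""
    chains: list[RawChain] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = validate_sequence(str(rec.seq).replace(" ", ""),
                                strict=strict,
                                fallback_residue=fallback_residue)
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has empty sequence")
        chains.append(RawChain(id=rec.id, sequence=seq))
    if not chains:
        raise FormatError(f"no FASTA records in {path}")
    return chains


def write_fasta(chains: Iterable[RawChain], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="")
               for c in chains]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# WOP profiles
# ---------------------------------------------------------------------------

def read_wop(path: str | Path, dialect: str = "psiblast-ascii",
             chain: RawChain | None = None) -> WopMatrix:
    """Read a per-residue WOP matrix.

    dialect "psiblast-ascii": the classic ASCII PSSM whose second block of 20
    columns carries the weighted observation percentages; columns are
    reordered from PSI-BLAST's native amino-acid order to alphabetical.
    dialect "tsv": a plain table of 20 numeric columns per residue, already in
    alphabetical order (comment lines starting with '#' ignored).
    """
    if dialect == "psiblast-ascii":
        matrix = _read_wop_psiblast(Path(path))
    elif dialect == "tsv":
        matrix = _read_wop_tsv(Path(path))
    else:
        raise ValueError(f"unknown WOP dialect {dialect!r}")
    if chain is not None and len(matrix) != len(chain):
        raise FormatError(
            f"WOP channel length {len(matrix)} does not match chain "
            f"{chain.id!r} length {len(chain)}")
    return matrix


def _read_wop_psiblast(path: Path) -> WopMatrix:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            # data lines start "<pos> <AA> <20 log-odds> <20 WOP> ..."
            if len(tok) < 42 or not tok[0].isdigit() or len(tok[1]) != 1:
                continue
            try:
                wop = [float(x) for x in tok[22:42]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric WOP cell ({exc})") from exc
            rows.append([wop[j] for j in _PSIBLAST_TO_ALPHA])
    if not rows:
        raise FormatError(f"no profile rows found in {path}")
    return WopMatrix(np.array(rows))


def _read_wop_tsv(path: Path) -> WopMatrix:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) != 20:
                raise FormatError(
                    f"{path}:{lineno}: expected 20 columns, got {len(tok)}")
            try:
                rows.append([float(x) for x in tok])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell ({exc})") from exc
    if not rows:
        raise FormatError(f"no WOP rows found in {path}")
    return WopMatrix(np.array(rows))


def write_wop_tsv(matrix: WopMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# WOP percentages, columns " + " ".join(AA_ALPHABET) + "\n")
        for row in matrix.values:
            fh.write("\t".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# SS / accessibility tables
# ---------------------------------------------------------------------------

def read_ss_rsa(path: str | Path, kind: str = "rsa",
                chain: RawChain | None = None) -> SsRsaTable:
    """Read a per-residue table of SS label and accessibility value.

    Data lines carry the SS label and the value in their last two columns, so
    both bare two-column files and files with leading position/residue columns
    parse. ``kind`` is "rsa" (relative, in [0,1]) or "asa" (raw Å²); a
    ``# kind: asa`` comment header overrides the argument.
    """
    if kind not in ("rsa", "asa"):
        raise ValueError(f"kind must be 'rsa' or 'asa', got {kind!r}")
    is_asa = kind == "asa"
    ss: list[str] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "kind" in line.lower():
                    is_asa = "asa" in line.lower().split("kind")[-1]
                continue
            tok = line.split()
            if len(tok) < 2:
                raise FormatError(f"{path}:{lineno}: need SS label and value")
            label = tok[-2].upper()
            try:
                val = float(tok[-1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric accessibility") from exc
            ss.append(label)
            vals.append(val)
    table = SsRsaTable("".join(ss), np.array(vals), is_asa=is_asa)
    if chain is not None and len(table) != len(chain):
        raise FormatError(
            f"SS/RSA channel length {len(table)} does not match chain "
            f"{chain.id!r} length {len(chain)}")
    return table


def write_ss_rsa(table: SsRsaTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {'asa' if table.is_asa else 'rsa'}\n")
        for s, v in zip(table.ss, table.values):
            fh.write(f"{s}\t{v:.6f}\n")


# ---------------------------------------------------------------------------
# Dipeptide scale
# ---------------------------------------------------------------------------

def read_dipeptide_scale(path: str | Path,
                         normalized: bool | None = None) -> DipeptideScale:
    """Read a 3-column TSV dipeptide scale (aa1, aa2, value).

    ``normalized=None`` infers the flag: the scale is treated as already
    renormalized when every value lies strictly inside (-1, 1).
    """
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns (aa1 aa2 value)")
            a, b = tok[0].upper(), tok[1].upper()
            if a not in AA_ALPHABET or b not in AA_ALPHABET:
                raise FormatError(f"{path}:{lineno}: unknown residue pair "
                                  f"{a}{b}")
            pair = a + b
            if pair in values:
                raise FormatError(f"{path}:{lineno}: duplicate pair {pair}")
            values[pair] = float(tok[2])
    if not values:
        raise FormatError(f"no scale entries in {path}")
    if normalized is None:
        normalized = all(-1 < v < 1 for v in values.values())
    return DipeptideScale(values, normalized=normalized)


def write_dipeptide_scale(scale: DipeptideScale, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# aa1\taa2\tvalue\n")
        for pair in sorted(scale.values):
            fh.write(f"{pair[0]}\t{pair[1]}\t{scale.values[pair]:.8g}\n")


# ---------------------------------------------------------------------------
# Fragment datasets
# ---------------------------------------------------------------------------

def read_fragment_dataset(path: str | Path,
                          strict: bool = True) -> list[FragmentRecord]:
    """Read whitespace-separated ``PEPTIDE label`` lines.

    Labels: 1/epitope/pos(...) mark epitopes, 0/non-epitope/neg(...) mark
    non-epitopes. An empty file returns an empty list with a warning.
    """
    records: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 2:
                raise FormatError(
                    f"{path}:{lineno}: need peptide and label columns")
            peptide = validate_sequence(tok[0], strict=strict)
            label_tok = tok[1].lower()
            if label_tok in EPITOPE_LABELS:
                label = True
            elif label_tok in NON_EPITOPE_LABELS:
                label = False
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown label token {tok[1]!r}")
            if len(peptide) != 20:
                raise FormatError(
                    f"{path}:{lineno}: peptide length {len(peptide)} != 20")
            records.append(FragmentRecord(peptide=peptide, label=label))
    if not records:
        warnings.warn(f"fragment dataset {path} is empty", stacklevel=2)
    return records


def write_fragment_dataset(records: Iterable[FragmentRecord],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.peptide}\t{1 if rec.label else 0}\n")


def count_labels(records: Sequence[FragmentRecord]) -> tuple[int, int]:
    """(#epitope, #non-epitope) in a fragment dataset."""
    n_pos = sum(r.label for r in records)
    return n_pos, len(records) - n_pos


# ---------------------------------------------------------------------------
# Propensity profiles and generic tables
# ---------------------------------------------------------------------------

def write_profile(sequence: str, propensities: Sequence[float],
                  path: str | Path, precision: int = 6) -> None:
    """Write a per-residue propensity profile as TSV (1-based positions)."""
    if len(sequence) != len(propensities):
        raise FormatError(
            f"profile length {len(propensities)} does not match sequence "
            f"length {len(sequence)}")
    with open(path, "w") as fh:
        fh.write("position\tresidue\tpropensity\n")
        for i, (aa, p) in enumerate(zip(sequence, propensities), 1):
            fh.write(f"{i}\t{aa}\t{p:.{precision}f}\n")


def read_profile(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a propensity profile TSV; returns (sequence, propensities)."""
    seq: list[str] = []
    props: list[float] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("position"):
            raise FormatError(f"{path}: missing profile header")
        for lineno, line in enumerate(fh, 2):
            line = line.strip()
            if not line:
                continue
            tok = line.split("\t")
            if len(tok) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            seq.append(tok[1])
            props.append(float(tok[2]))
    return "".join(seq), np.array(props)


def read_two_column_table(path: str | Path) -> dict[str, float]:
    """Read a (residue, value) override table (background freqs, ref areas)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out[tok[0].upper()] = float(tok[1])
    return out


def save_model(bundle: object, path: str | Path) -> None:
    """Serialize a trained model bundle (joblib)."""
    joblib.dump(bundle, str(path))


def load_model(path: str | Path) -> object:
    return joblib.load(str(path))
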