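"""Synthetic fixture generation: labeled fragment datasets and annotated
chains with planted epitope structure.

Every input the pipeline consumes can be fabricated here, seeded and
bit-reproducible, with class signal planted in each feature family:

* sequence composition — epitope peptides over-sample a hydrophilic residue
  set whose dipeptides score high on the generated scale (drives the
  dipeptide-scale features);
* motifs — short epitope motifs pasted into epitope fragments (drives the
  library-similarity features);
* accessibility — epitope residues drawn more exposed (drives RSA features);
* secondary structure — epitope windows biased toward coil;
* conservation — profile columns more concentrated inside epitopes, with a
  configurable rate of all-zero rows to exercise the fallback path.

With all effect sizes zero, the two classes are exchangeable: a classifier
trained on such a fixture should perform at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import ROBINSON_ROBINSON
from .features import Fragment
from .io_formats import (AA_ALPHABET, DipeptideScale, FragmentRecord,
                         RawChain, SsRsaTable, WopMatrix,
                         write_dipeptide_scale, write_fasta,
                         write_fragment_dataset, write_ss_rsa, write_wop_tsv)
from .similarity import FragmentLibrary

#: Residues over-sampled in epitope fragments (hydrophilic, surface-biased).
FAVORED_RESIDUES = "DEKNQRST"

_BG_P = np.array([ROBINSON_ROBINSON[aa] for aa in AA_ALPHABET])
_BG_P = _BG_P / _BG_P.sum()


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded recipe for one synthetic study condition.

    Effect sizes of 0 make the epitope and non-epitope classes exchangeable;
    the defaults are a strong, clearly learnable condition.
    """

    seed: int = 0
    n_epitope: int = 200
    n_non_epitope: int = 200
    n_chains: int = 3
    chain_length_range: tuple[int, int] = (50, 80)
    epitope_length_range: tuple[int, int] = (10, 20)
    delta_raap: float = 0.8     # epitope residue-composition bias
    delta_rsa: float = 0.3      # exposure-probability shift inside epitopes
    delta_con: float = 0.5      # profile-concentration shift inside epitopes
    delta_ss: float = 0.3       # coil-content shift inside epitopes
    motifs: tuple[str, ...] = ("KDERTN", "QSTKDE", "NREQSD")
    motif_prob: float = 0.9     # chance an epitope fragment carries a motif
    zero_row_rate: float = 0.05  # all-zero WOP rows, exercises the fallback
    rsa_noise: float = 0.15
    con_noise: float = 0.5

    def __post_init__(self) -> None:
        for m in self.motifs:
            if len(m) > 20:
                raise ValueError(f"motif {m!r} longer than a 20-mer")
            if set(m) - set(AA_ALPHABET):
                raise ValueError(f"motif {m!r} has non-canonical residues")

    def null(self) -> "FixtureSpec":
        """The matched no-signal condition (all effect sizes zero)."""
        return FixtureSpec(seed=self.seed, n_epitope=self.n_epitope,
                           n_non_epitope=self.n_non_epitope,
                           n_chains=self.n_chains,
                           chain_length_range=self.chain_length_range,
                           delta_raap=0.0, delta_rsa=0.0, delta_con=0.0,
                           delta_ss=0.0, motif_prob=0.0,
                           zero_row_rate=self.zero_row_rate)


@dataclass
class FragmentFixture:
    records: list[FragmentRecord]
    fragments: list[Fragment]
    labels: np.ndarray
    scale: DipeptideScale
    library: FragmentLibrary


@dataclass
class ChainFixture:
    chain: RawChain
    ss_rsa: SsRsaTable
    wop: WopMatrix
    truth: np.ndarray  # bool, True = epitope residue


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def make_scale(spec: FixtureSpec) -> DipeptideScale:
    """Complete 400-entry scale: favored-residue dipeptides score higher."""
    rng = np.random.default_rng(spec.seed + 101)
    values = {}
    for a in AA_ALPHABET:
        for b in AA_ALPHABET:
            bonus = (spec.delta_raap
                     if a in FAVORED_RESIDUES and b in FAVORED_RESIDUES
                     else -spec.delta_raap) / 2.0
            values[a + b] = float(np.tanh(rng.normal(0.0, 0.3) + bonus)
                                  * 0.99)
    return DipeptideScale(values, normalized=True)


def _residue_probs(epitope: bool, delta: float) -> np.ndarray:
    if not epitope or delta == 0:
        return _BG_P
    w = np.array([1.0 + delta if aa in FAVORED_RESIDUES else 1.0
                  for aa in AA_ALPHABET]) * _BG_P
    return w / w.sum()


def _sample_peptide(rng, length: int, epitope: bool,
                    spec: FixtureSpec) -> str:
    probs = _residue_probs(epitope, spec.delta_raap)
    pep = list(rng.choice(list(AA_ALPHABET), size=length, p=probs))
    if epitope and spec.motifs and rng.random() < spec.motif_prob:
        motif = spec.motifs[rng.integers(len(spec.motifs))]
        if len(motif) <= length:
            start = rng.integers(length - len(motif) + 1)
            pep[start:start + len(motif)] = list(motif)
    return "".join(pep)


def _sample_ss(rng, length: int, epitope: bool, spec: FixtureSpec) -> str:
    """Run-structured SS labels; epitopes biased toward coil."""
    coil_shift = spec.delta_ss / 2.0 if epitope else 0.0
    p = np.array([(1 - coil_shift) / 3, (1 - coil_shift) / 3,
                  1 / 3 + 2 * coil_shift / 3])
    p = p / p.sum()
    labels: list[str] = []
    while len(labels) < length:
        cls = "HEC"[rng.choice(3, p=p)]
        run = 1 + rng.geometric(0.35)
        labels.extend(cls * run)
    return "".join(labels[:length])


def _sample_rsa(rng, length: int, epitope: bool,
                spec: FixtureSpec) -> np.ndarray:
    mu = 0.5 + (spec.delta_rsa / 2.0 if epitope else -spec.delta_rsa / 2.0)
    return np.clip(rng.normal(mu, spec.rsa_noise, size=length), 0.0, 1.0)


def _sample_conservation(rng, length: int, epitope: bool,
                         spec: FixtureSpec) -> np.ndarray:
    mu = 1.0 + (spec.delta_con if epitope else 0.0)
    return rng.normal(mu, spec.con_noise, size=length)


def _sample_wop_row(rng, aa: str, concentrated: bool,
                    spec: FixtureSpec) -> np.ndarray:
    """Dirichlet-style percentages with extra mass on the native residue."""
    conc = np.ones(20)
    own = AA_ALPHABET.index(aa)
    conc[own] += 8.0 + (24.0 * spec.delta_con if concentrated else 0.0)
    row = rng.dirichlet(conc) * 100.0
    return row


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_fragment_dataset(spec: FixtureSpec) -> FragmentFixture:
    """Labeled 20-mers with per-fragment channels, scale and library."""
    rng = np.random.default_rng(spec.seed)
    scale = make_scale(spec)
    records: list[FragmentRecord] = []
    fragments: list[Fragment] = []
    labels = np.array([True] * spec.n_epitope
                      + [False] * spec.n_non_epitope)
    for i, lab in enumerate(labels):
        pep = _sample_peptide(rng, 20, lab, spec)
        rsa = _sample_rsa(rng, 20, lab, spec)
        fragments.append(Fragment(
            peptide=pep,
            ss=_sample_ss(rng, 20, lab, spec),
            rsa=rsa,
            exposure=rsa >= 0.25,
            conservation=_sample_conservation(rng, 20, lab, spec),
            source_id=f"frag{i}"))
        records.append(FragmentRecord(peptide=pep, label=bool(lab)))
    library = FragmentLibrary(
        epitopes=[f.peptide for f, lab in zip(fragments, labels) if lab],
        non_epitopes=[f.peptide for f, lab in zip(fragments, labels)
                      if not lab],
        provenance=f"fixture-seed{spec.seed}")
    return FragmentFixture(records=records, fragments=fragments,
                           labels=labels, scale=scale, library=library)


def gen_chain_with_epitopes(spec: FixtureSpec, index: int = 0,
                            length: int | None = None,
                            ) -> ChainFixture:
    """One chain with embedded epitope segments and all channels.

    Epitope residues carry the planted composition, motif, exposure, SS and
    conservation signals; the WOP matrix is more concentrated inside
    epitopes and all-zero rows are injected at ``spec.zero_row_rate``.
    """
    rng = np.random.default_rng(spec.seed + 1000 * (index + 1))
    if length is None:
        lo, hi = spec.chain_length_range
        length = int(rng.integers(lo, hi + 1))
    if length < 20:
        raise ValueError("chain length must be at least 20")

    truth = np.zeros(length, dtype=bool)
    elo, ehi = spec.epitope_length_range
    ep_len = int(rng.integers(elo, min(ehi, length) + 1))
    start = int(rng.integers(length - ep_len + 1))
    truth[start:start + ep_len] = True

    seq = list(_sample_peptide(rng, length, False, spec))
    # overwrite the epitope stretch with epitope-style residues (+ motif)
    seq[start:start + ep_len] = list(
        _sample_peptide(rng, ep_len, True, spec))
    sequence = "".join(seq)

    ss = list(_sample_ss(rng, length, False, spec))
    rsa = _sample_rsa(rng, length, False, spec)
    ss_ep = _sample_ss(rng, ep_len, True, spec)
    rsa_ep = _sample_rsa(rng, ep_len, True, spec)
    ss[start:start + ep_len] = list(ss_ep)
    rsa[start:start + ep_len] = rsa_ep

    rows = np.vstack([
        _sample_wop_row(rng, aa, concentrated=bool(t), spec=spec)
        for aa, t in zip(sequence, truth)])
    zero = rng.random(length) < spec.zero_row_rate
    rows[zero] = 0.0

    chain = RawChain(id=f"synthchain{index}", sequence=sequence)
    return ChainFixture(chain=chain,
                        ss_rsa=SsRsaTable("".join(ss), rsa, is_asa=False),
                        wop=WopMatrix(rows),
                        truth=truth)


# ---------------------------------------------------------------------------
# On-disk fixture sets
# ---------------------------------------------------------------------------

def write_fragment_channels(fragments: list[Fragment], path) -> None:
    """Per-fragment channel table: fragment, pos, ss, rsa, conservation."""
    with open(path, "w") as fh:
        fh.write("fragment\tpos\tss\trsa\tconservation\n")
        for i, frag in enumerate(fragments):
            for j in range(len(frag)):
                fh.write(f"{i}\t{j + 1}\t{frag.ss[j]}\t{frag.rsa[j]:.6f}\t"
                         f"{frag.conservation[j]:.6f}\n")


def read_fragment_channels(path, records: list[FragmentRecord],
                           ) -> list[Fragment]:
    """Re-attach channels written by :func:`write_fragment_channels`."""
    per_frag: dict[int, list[tuple[str, float, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("fragment"):
            raise ValueError(f"{path}: missing channel header")
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            per_frag.setdefault(int(tok[0]), []).append(
                (tok[2], float(tok[3]), float(tok[4])))
    fragments = []
    for i, rec in enumerate(records):
        if i not in per_frag or len(per_frag[i]) != 20:
            raise ValueError(f"{path}: fragment {i} lacks 20 channel rows")
        ss = "".join(row[0] for row in per_frag[i])
        rsa = np.array([row[1] for row in per_frag[i]])
        con = np.array([row[2] for row in per_frag[i]])
        fragments.append(Fragment(peptide=rec.peptide, ss=ss, rsa=rsa,
                                  exposure=rsa >= 0.25, conservation=con,
                                  source_id=f"frag{i}"))
    return fragments


def write_fixture_dir(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Materialize a complete fixture set under ``outdir``.

    Writes the fragment dataset (+ channels), dipeptide scale, chain FASTA
    and, per chain, SS/RSA and WOP tables plus the truth intervals. Returns
    the path of every file written.
    """
    from .pipeline import write_truth_intervals

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frag = gen_fragment_dataset(spec)
    paths["fragments"] = outdir / "fragments.tsv"
    write_fragment_dataset(frag.records, paths["fragments"])
    paths["fragment_channels"] = outdir / "fragment_channels.tsv"
    write_fragment_channels(frag.fragments, paths["fragment_channels"])
    paths["scale"] = outdir / "scale.tsv"
    write_dipeptide_scale(frag.scale, paths["scale"])

    chains = [gen_chain_with_epitopes(spec, i) for i in range(spec.n_chains)]
    paths["fasta"] = outdir / "chains.fasta"
    write_fasta([c.chain for c in chains], paths["fasta"])
    for c in chains:
        cid = c.chain.id
        paths[f"{cid}_ss_rsa"] = outdir / f"{cid}_ss_rsa.tsv"
        write_ss_rsa(c.ss_rsa, paths[f"{cid}_ss_rsa"])
        paths[f"{cid}_wop"] = outdir / f"{cid}_wop.tsv"
        write_wop_tsv(c.wop, paths[f"{cid}_wop"])
        paths[f"{cid}_truth"] = outdir / f"{cid}_truth.tsv"
        write_truth_intervals(c.truth, paths[f"{cid}_truth"])
    return paths
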