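"""Stage 2: sliding-window scoring and per-residue propensity aggregation.

A chain of length L >= 20 is cut into L-19 overlapping 20-mer windows (step
1), each window is scored by the fragment classifier, and every residue
inherits the scores of all windows covering it — between 1 score at either
terminus and 20 for interior residues. The per-residue score multiset is
collapsed to a propensity by one of four schemes:

* ``max``     — the largest score;
* ``average`` — the mean;
* ``median``  — the median (mean of the middle two for even counts);
* ``distance``— the mean of the k scores farthest from the 0.5 decision
  boundary (all available scores when fewer than k; k = 20 reduces to the
  average scheme). The default is the distance scheme with k = 16.
"""

from __future__ import annotations

import numpy as np

from .annotation import AnnotatedChain
from .features import Fragment, featurize_fragments
from .io_formats import DipeptideScale, FormatError
from .svm_core import TrainedModel

WINDOW = 20
SCHEMES = ("max", "average", "median", "distance")
DEFAULT_SCHEME = "distance"
DEFAULT_K = 16


def make_windows(annotated: AnnotatedChain) -> list[Fragment]:
    """All 20-mer windows of a chain, annotation channels sliced alongside.

    Chains shorter than 20 residues are rejected: the feature machinery is
    defined on 20-mers and no padding rule exists.
    """
    L = len(annotated)
    if L < WINDOW:
        raise FormatError(
            f"chain {annotated.chain.id!r} has {L} residues; at least "
            f"{WINDOW} are required")
    frags = []
    for start in range(L - WINDOW + 1):
        end = start + WINDOW
        frags.append(Fragment(
            peptide=annotated.chain.sequence[start:end],
            ss=annotated.ss[start:end],
            rsa=annotated.rsa[start:end],
            exposure=annotated.exposure[start:end],
            conservation=annotated.conservation[start:end],
            source_id=annotated.chain.id,
            offset=start + 1))
    return frags


def covering_windows(i: int, L: int) -> tuple[int, int]:
    """1-based inclusive window-offset range covering residue i of a chain."""
    if not 1 <= i <= L:
        raise ValueError(f"residue {i} outside chain of length {L}")
    return max(1, i - WINDOW + 1), min(i, L - WINDOW + 1)


def residue_score_sets(window_scores: np.ndarray, L: int) -> list[np.ndarray]:
    """Per-residue multisets of covering-window scores, window order kept."""
    window_scores = np.asarray(window_scores, dtype=float)
    if len(window_scores) != L - WINDOW + 1:
        raise ValueError(
            f"expected {L - WINDOW + 1} window scores for chain length {L}, "
            f"got {len(window_scores)}")
    out = []
    for i in range(1, L + 1):
        lo, hi = covering_windows(i, L)
        out.append(window_scores[lo - 1:hi])
    return out


def aggregate(scores: np.ndarray, scheme: str = DEFAULT_SCHEME,
              k: int = DEFAULT_K) -> float:
    """Collapse one residue's window scores to a single propensity."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score multiset")
    if scheme == "max":
        return float(scores.max())
    if scheme == "average":
        return float(scores.mean())
    if scheme == "median":
        return float(np.median(scores))
    if scheme == "distance":
        if not 1 <= k <= WINDOW:
            raise ValueError(f"k must lie in [1, {WINDOW}], got {k}")
        if k >= scores.size:
            # all scores selected: bit-identical to the average scheme
            return float(scores.mean())
        # k scores farthest from 0.5; ties resolved toward earlier windows
        order = np.argsort(-np.abs(scores - 0.5), kind="stable")
        return float(scores[order[:k]].mean())
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def profile_from_window_scores(window_scores: np.ndarray, L: int,
                               scheme: str = DEFAULT_SCHEME,
                               k: int = DEFAULT_K) -> np.ndarray:
    """Per-residue propensities from the vector of window scores."""
    return np.array([aggregate(s, scheme=scheme, k=k)
                     for s in residue_score_sets(window_scores, L)])


def predict_chain(annotated: AnnotatedChain, model: TrainedModel,
                  scale: DipeptideScale, scheme: str = DEFAULT_SCHEME,
                  k: int = DEFAULT_K,
                  similarity_mode: str = "distinct") -> np.ndarray:
    """End-to-end propensity profile for one annotated chain."""
    if model.library is None:
        raise ValueError("model carries no similarity library")
    windows = make_windows(annotated)
    X = featurize_fragments(windows, None, model.library, scale,
                            similarity_mode=similarity_mode,
                            manifest=(model.manifest
                                      if len(model.manifest) else None))
    scores = model.scores(X)
    return profile_from_window_scores(scores, len(annotated),
                                      scheme=scheme, k=k)


def train_fragment_model(fragments: list[Fragment], labels,
                         scale: DipeptideScale,
                         config=None, manifest: list[str] | None = None,
                         similarity_mode: str = "distinct",
                         wop_fallback_table=None,
                         provenance: str = "training") -> TrainedModel:
    """Train a fragment classifier from annotated, labeled 20-mers.

    The similarity library is built from the training fragments themselves
    and each fragment is excluded from its own similarity features (the
    cross-validation hygiene rule); the library then travels with the model
    so new chains are featurized against the same reference set.
    """
    import numpy as _np

    from .features import FEATURE_NAMES
    from .similarity import FragmentLibrary
    from .svm_core import train as _train

    labels = _np.asarray(labels, dtype=bool)
    library = FragmentLibrary(
        epitopes=[f.peptide for f, lab in zip(fragments, labels) if lab],
        non_epitopes=[f.peptide for f, lab in zip(fragments, labels)
                      if not lab],
        provenance=provenance)
    X = featurize_fragments(fragments, list(labels), library, scale,
                            similarity_mode=similarity_mode,
                            exclude_self=True, manifest=manifest)
    model = _train(X, labels, config,
                   manifest=list(manifest) if manifest else list(FEATURE_NAMES))
    model.library = library
    model.library_fingerprint = library.fingerprint()
    model.wop_fallback_table = wop_fallback_table
    return model


# ---------------------------------------------------------------------------
# Truth files (per-residue 0/1 TSV or 1-based inclusive intervals)
# ---------------------------------------------------------------------------

def read_truth(path, L: int | None = None) -> np.ndarray:
    """Read per-residue epitope truth.

    Two layouts are accepted: one 0/1 value per line (optionally preceded by
    a position column), or interval lines ``start<TAB>end`` (1-based,
    inclusive; requires ``L``).
    """
    lines = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                lines.append(line.split())
    if not lines:
        raise FormatError(f"empty truth file {path}")
    # interval layout: every line "start end", 1 <= start <= end, end > 1
    # (a per-residue file's last column is always 0/1, so it never matches)
    try:
        is_interval = all(len(t) == 2 for t in lines) and all(
            1 <= int(t[0]) <= int(t[1]) and int(t[1]) > 1 for t in lines)
    except ValueError:
        is_interval = False
    if is_interval:
        if L is None:
            raise ValueError("interval truth requires the chain length")
        truth = np.zeros(L, dtype=bool)
        for t in lines:
            start, end = int(t[0]), int(t[1])
            if not 1 <= start <= end <= L:
                raise FormatError(
                    f"truth interval [{start}, {end}] outside chain of "
                    f"length {L}")
            truth[start - 1:end] = True
        return truth
    vals = [int(t[-1]) for t in lines]
    if set(vals) - {0, 1}:
        raise FormatError(f"truth values must be 0/1 in {path}")
    truth = np.array(vals, dtype=bool)
    if L is not None and len(truth) != L:
        raise FormatError(
            f"truth length {len(truth)} does not match chain length {L}")
    return truth


def write_truth_intervals(truth: np.ndarray, path) -> None:
    """Write epitope truth as 1-based inclusive intervals."""
    truth = np.asarray(truth, dtype=bool)
    with open(path, "w") as fh:
        fh.write("# 1-based inclusive epitope intervals\n")
        start = None
        for i, v in enumerate(truth, 1):
            if v and start is None:
                start = i
            elif not v and start is not None:
                fh.write(f"{start}\t{i - 1}\n")
                start = None
        if start is not None:
            fh.write(f"{start}\t{len(truth)}\n")
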