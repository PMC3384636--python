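"""Feature encoding of annotated 20-mer peptide windows.

Each fragment is described by 198 named features organized in 11 groups:

==== ======================================== =====
 #   group                                    count
==== ======================================== =====
 1   secondary structure (SS)                   8
 2   relative accessibility (RA)               33
 3   dipeptide antigenicity scale (RP)         30
 4   conservation score (CS)                   29
 5   SS x RA                                   12
 6   SS x CS                                    6
 7   SS x RP                                    6
 8   RP x RA                                   30
 9   RP x CS                                   28
10   SS x RA x RP                               6
11   similarity to fragment libraries (SIM)    10
==== ======================================== =====

Conventions frozen here for model portability:

* canonical order = group order above; within a group, the listing order of
  the definitions; sliding-window features by window size n ascending with
  max before min; SS classes in H, E, C order; buried before exposed.
* class- or exposure-restricted means over an empty residue set are 0, and
  counts over an empty set are 0.
* the "longest segment" of a class and the extremal sliding window are the
  leftmost ones on ties.
* sliding windows are counted in residues (n = 5..18); on the dipeptide-score
  channel a window of n residues covers its n-1 internal dipeptides.
* for residue-restricted dipeptide-scale features each residue carries the
  mean score of the dipeptides containing it (one at the termini, two
  inside); whole-window and sliding statistics use the raw 19-score sequence.
* entropies are natural-log sums of class fractions (values <= 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DipeptideScale, FormatError, FragmentRecord
from .similarity import FragmentLibrary, topk_similarity

WINDOW_SIZES = tuple(range(5, 19))  # n = 5..18
SS_ORDER = "HEC"
EXPOSURE_ORDER = ("Bd", "Ed")  # buried, exposed

GROUP_NAMES = ("SS", "RA", "RP", "CS", "SS+RA", "SS+CS", "SS+RP",
               "RP+RA", "RP+CS", "SS+RA+RP", "SIM")


@dataclass
class Fragment:
    """A 20-residue window with all aligned annotation channels."""

    peptide: str
    ss: str
    rsa: np.ndarray
    exposure: np.ndarray  # bool, True = exposed
    conservation: np.ndarray
    source_id: str | None = None
    offset: int | None = None  # 1-based start in the source chain

    def __post_init__(self) -> None:
        n = len(self.peptide)
        for name in ("ss", "rsa", "exposure", "conservation"):
            if len(getattr(self, name)) != n:
                raise FormatError(
                    f"fragment channel {name!r} length != {n}")
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=bool)
        self.conservation = np.asarray(self.conservation, dtype=float)

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass
class FeatureVector:
    """Ordered, named feature values for one fragment."""

    values: np.ndarray
    names: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if not len(self.values) == len(self.names) == len(self.groups):
            raise ValueError("values/names/groups must be parallel")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def select(self, manifest: list[str]) -> "FeatureVector":
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in manifest if n not in index]
        if missing:
            raise KeyError(f"manifest names not in vector: {missing[:5]}")
        idx = [index[n] for n in manifest]
        return FeatureVector(self.values[idx],
                             tuple(manifest),
                             tuple(self.groups[i] for i in idx))


# ---------------------------------------------------------------------------
# Canonical feature naming
# ---------------------------------------------------------------------------

def _slide_names(prefix: str) -> list[str]:
    out = []
    for n in WINDOW_SIZES:
        out.append(f"max_{prefix}_slide_{n}")
        out.append(f"min_{prefix}_slide_{n}")
    return out


def _cross_slide_names(which: str) -> list[str]:
    out = []
    for n in WINDOW_SIZES:
        out.append(f"avg_RAAP_max_{which}_slide_{n}")
        out.append(f"avg_RAAP_min_{which}_slide_{n}")
    return out


def feature_catalog() -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(names, group tags) of the full 198-feature vector, canonical order."""
    names: list[str] = []
    groups: list[str] = []

    def add(group: str, feats: list[str]) -> None:
        names.extend(feats)
        groups.extend([group] * len(feats))

    add("SS", [f"content_{c}" for c in SS_ORDER] + ["entropy_SS"]
        + [f"NumSeg_{c}" for c in SS_ORDER] + ["NumSeg_SS"])
    add("RA", ["content_Bd", "content_Ed", "entropy_RSA",
               "RSA_Bd", "RSA_Ed"] + _slide_names("RSA"))
    add("RP", ["avg_RAAP", "sd_RAAP"] + _slide_names("RAAP"))
    add("CS", ["avg_CON"] + _slide_names("CON"))
    add("SS+RA", [f"Num_{c}_{e}" for c in SS_ORDER for e in EXPOSURE_ORDER]
        + [f"RSA_{c}" for c in SS_ORDER]
        + [f"RSA_max_segment_{c}" for c in SS_ORDER])
    add("SS+CS", [f"CON_{c}" for c in SS_ORDER]
        + [f"CON_max_segment_{c}" for c in SS_ORDER])
    add("SS+RP", [f"RAAP_{c}" for c in SS_ORDER]
        + [f"RAAP_max_segment_{c}" for c in SS_ORDER])
    add("RP+RA", ["RAAP_Bd", "RAAP_Ed"] + _cross_slide_names("RSA"))
    add("RP+CS", _cross_slide_names("CON"))
    add("SS+RA+RP", [f"RAAP_{c}_{e}" for c in SS_ORDER
                     for e in EXPOSURE_ORDER])
    add("SIM", [f"max_similarity_epitope_{k}" for k in range(1, 6)]
        + [f"max_similarity_non-epitope_{k}" for k in range(1, 6)])
    return tuple(names), tuple(groups)


FEATURE_NAMES, FEATURE_GROUPS = feature_catalog()
N_FEATURES = len(FEATURE_NAMES)


def group_cardinalities() -> dict[str, int]:
    out: dict[str, int] = {}
    for g in FEATURE_GROUPS:
        out[g] = out.get(g, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def segments(labels: str) -> list[tuple[str, int, int]]:
    """Maximal runs of identical labels as (label, start, length), 0-based."""
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return runs


def segment_counts(ss: str) -> dict[str, int]:
    """Number of maximal segments per SS class, plus the total.

    Defined for arbitrary-length label strings, not just 20-mers.
    """
    bad = sorted(set(ss) - set(SS_ORDER))
    if bad:
        raise ValueError(f"illegal secondary-structure labels: {bad}")
    counts = {c: 0 for c in SS_ORDER}
    for label, _, _ in segments(ss):
        counts[label] += 1
    counts["total"] = sum(counts[c] for c in SS_ORDER)
    return counts


def class_content_entropy(labels: "str | np.ndarray",
                          classes: "str | tuple",
                          ) -> tuple[dict, float]:
    """Per-class fractions and the natural-log entropy sum (values <= 0)."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label sequence")
    n = len(labels)
    contents = {c: labels.count(c) / n for c in classes}
    entropy = sum(p * np.log(p) for p in contents.values() if p > 0)
    return contents, float(entropy)


def sliding_means(values: np.ndarray, n: int) -> np.ndarray:
    """Means of all contiguous windows of size n."""
    values = np.asarray(values, dtype=float)
    if n < 1 or n > len(values):
        raise ValueError(
            f"window size {n} invalid for sequence of length {len(values)}")
    csum = np.concatenate(([0.0], np.cumsum(values)))
    return (csum[n:] - csum[:-n]) / n


def sliding_stat(values: np.ndarray, n: int, which: str) -> float:
    """Extremum over all size-n windows of the window mean."""
    means = sliding_means(values, n)
    if which == "max":
        return float(means.max())
    if which == "min":
        return float(means.min())
    raise ValueError(f"which must be 'min' or 'max', got {which!r}")


def _restricted_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Mean over the selected residues; 0 when the selection is empty."""
    if not mask.any():
        return 0.0
    return float(values[mask].mean())


def _longest_run(ss: str, cls: str) -> tuple[int, int] | None:
    """(start, length) of the leftmost longest run of ``cls``; None if absent."""
    best: tuple[int, int] | None = None
    for label, start, length in segments(ss):
        if label == cls and (best is None or length > best[1]):
            best = (start, length)
    return best


# ---------------------------------------------------------------------------
# Dipeptide-scale channels
# ---------------------------------------------------------------------------

def dipeptide_scores(peptide: str, scale: DipeptideScale,
                     strict: bool = True) -> np.ndarray:
    """The L-1 overlapping-dipeptide scale values of a peptide."""
    return np.array([scale.lookup(peptide[i:i + 2], strict=strict)
                     for i in range(len(peptide) - 1)])


def per_residue_raap(dipep: np.ndarray) -> np.ndarray:
    """Residue-level scale track: mean of the dipeptide scores touching each
    residue (one at either terminus, two inside)."""
    m = len(dipep) + 1
    out = np.empty(m)
    out[0] = dipep[0]
    out[-1] = dipep[-1]
    for i in range(1, m - 1):
        out[i] = 0.5 * (dipep[i - 1] + dipep[i])
    return out


def raap_stats(fragment: Fragment, scale: DipeptideScale,
               strict: bool = True) -> dict[str, float]:
    """avg/sd over the 19 dipeptide scores plus the 28 sliding extrema."""
    dipep = dipeptide_scores(fragment.peptide, scale, strict=strict)
    out = {"avg_RAAP": float(dipep.mean()),
           "sd_RAAP": float(dipep.std())}
    for n in WINDOW_SIZES:
        # an n-residue window covers n-1 consecutive dipeptides
        out[f"max_RAAP_slide_{n}"] = sliding_stat(dipep, n - 1, "max")
        out[f"min_RAAP_slide_{n}"] = sliding_stat(dipep, n - 1, "min")
    return out


def _window_mean_dipep(dipep: np.ndarray, start: int, n: int) -> float:
    """Mean dipeptide score inside the n-residue window starting at start."""
    return float(dipep[start:start + n - 1].mean())


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_features(fragment: Fragment,
                     library: FragmentLibrary,
                     scale: DipeptideScale,
                     similarity_mode: str = "distinct",
                     exclude_epitope_index: int | None = None,
                     exclude_non_epitope_index: int | None = None,
                     manifest: list[str] | None = None,
                     strict_scale: bool = True) -> FeatureVector:
    """Encode an annotated fragment as the canonical named feature vector.

    With a selection ``manifest`` the returned vector carries exactly the
    listed features, in manifest order.
    """
    f: dict[str, float] = {}
    ss, rsa, con = fragment.ss, fragment.rsa, fragment.conservation
    exposed = fragment.exposure
    buried = ~exposed

    # --- group 1: secondary structure
    contents, ent = class_content_entropy(ss, SS_ORDER)
    for c in SS_ORDER:
        f[f"content_{c}"] = contents[c]
    f["entropy_SS"] = ent
    segs = segment_counts(ss)
    for c in SS_ORDER:
        f[f"NumSeg_{c}"] = float(segs[c])
    f["NumSeg_SS"] = float(segs["total"])

    # --- group 2: accessibility
    exp_contents, exp_ent = class_content_entropy(
        ["Ed" if e else "Bd" for e in exposed], EXPOSURE_ORDER)
    f["content_Bd"] = exp_contents["Bd"]
    f["content_Ed"] = exp_contents["Ed"]
    f["entropy_RSA"] = exp_ent
    f["RSA_Bd"] = _restricted_mean(rsa, buried)
    f["RSA_Ed"] = _restricted_mean(rsa, exposed)
    for n in WINDOW_SIZES:
        f[f"max_RSA_slide_{n}"] = sliding_stat(rsa, n, "max")
        f[f"min_RSA_slide_{n}"] = sliding_stat(rsa, n, "min")

    # --- group 3: dipeptide scale
    dipep = dipeptide_scores(fragment.peptide, scale, strict=strict_scale)
    res_raap = per_residue_raap(dipep)
    f.update(raap_stats(fragment, scale, strict=strict_scale))

    # --- group 4: conservation
    f["avg_CON"] = float(con.mean())
    for n in WINDOW_SIZES:
        f[f"max_CON_slide_{n}"] = sliding_stat(con, n, "max")
        f[f"min_CON_slide_{n}"] = sliding_stat(con, n, "min")

    # --- group 5: SS x RA
    ss_arr = np.frombuffer(ss.encode(), dtype="S1").astype("U1")
    for c in SS_ORDER:
        cmask = ss_arr == c
        f[f"Num_{c}_Bd"] = float((cmask & buried).sum())
        f[f"Num_{c}_Ed"] = float((cmask & exposed).sum())
    for c in SS_ORDER:
        f[f"RSA_{c}"] = _restricted_mean(rsa, ss_arr == c)
    for c in SS_ORDER:
        run = _longest_run(ss, c)
        f[f"RSA_max_segment_{c}"] = (
            0.0 if run is None
            else float(rsa[run[0]:run[0] + run[1]].mean()))

    # --- group 6: SS x CS
    for c in SS_ORDER:
        f[f"CON_{c}"] = _restricted_mean(con, ss_arr == c)
    for c in SS_ORDER:
        run = _longest_run(ss, c)
        f[f"CON_max_segment_{c}"] = (
            0.0 if run is None
            else float(con[run[0]:run[0] + run[1]].mean()))

    # --- group 7: SS x RP
    for c in SS_ORDER:
        f[f"RAAP_{c}"] = _restricted_mean(res_raap, ss_arr == c)
    for c in SS_ORDER:
        run = _longest_run(ss, c)
        f[f"RAAP_max_segment_{c}"] = (
            0.0 if run is None
            else float(res_raap[run[0]:run[0] + run[1]].mean()))

    # --- group 8: RP x RA
    f["RAAP_Bd"] = _restricted_mean(res_raap, buried)
    f["RAAP_Ed"] = _restricted_mean(res_raap, exposed)
    for n in WINDOW_SIZES:
        means = sliding_means(rsa, n)
        f[f"avg_RAAP_max_RSA_slide_{n}"] = _window_mean_dipep(
            dipep, int(np.argmax(means)), n)
        f[f"avg_RAAP_min_RSA_slide_{n}"] = _window_mean_dipep(
            dipep, int(np.argmin(means)), n)

    # --- group 9: RP x CS
    for n in WINDOW_SIZES:
        means = sliding_means(con, n)
        f[f"avg_RAAP_max_CON_slide_{n}"] = _window_mean_dipep(
            dipep, int(np.argmax(means)), n)
        f[f"avg_RAAP_min_CON_slide_{n}"] = _window_mean_dipep(
            dipep, int(np.argmin(means)), n)

    # --- group 10: SS x RA x RP
    for c in SS_ORDER:
        cmask = ss_arr == c
        f[f"RAAP_{c}_Bd"] = _restricted_mean(res_raap, cmask & buried)
        f[f"RAAP_{c}_Ed"] = _restricted_mean(res_raap, cmask & exposed)

    # --- group 11: similarity
    ep, ne = topk_similarity(
        fragment.peptide, library, k=5, mode=similarity_mode,
        exclude_epitope_index=exclude_epitope_index,
        exclude_non_epitope_index=exclude_non_epitope_index)
    for k in range(1, 6):
        f[f"max_similarity_epitope_{k}"] = float(ep[k - 1])
        f[f"max_similarity_non-epitope_{k}"] = float(ne[k - 1])

    values = np.array([f[name] for name in FEATURE_NAMES])
    vec = FeatureVector(values, FEATURE_NAMES, FEATURE_GROUPS)
    if manifest is not None:
        vec = vec.select(manifest)
    return vec


def featurize_fragments(fragments: list[Fragment],
                        labels: list[bool] | None,
                        library: FragmentLibrary,
                        scale: DipeptideScale,
                        similarity_mode: str = "distinct",
                        exclude_self: bool = False,
                        manifest: list[str] | None = None,
                        ) -> np.ndarray:
    """Stack feature vectors into an (n_fragments, n_features) matrix.

    ``exclude_self=True`` applies the cross-validation hygiene rule: fragment
    i of the labeled set is assumed to be entry i of its side of the library
    (build the library from the same ordered fragments) and is excluded from
    its own similarity features.
    """
    if exclude_self and labels is None:
        raise ValueError("exclude_self requires labels")
    rows = []
    ep_seen = ne_seen = 0
    for i, frag in enumerate(fragments):
        ex_ep = ex_ne = None
        if exclude_self:
            if labels[i]:
                ex_ep, ep_seen = ep_seen, ep_seen + 1
            else:
                ex_ne, ne_seen = ne_seen, ne_seen + 1
        try:
            vec = extract_features(
                frag, library, scale, similarity_mode=similarity_mode,
                exclude_epitope_index=ex_ep,
                exclude_non_epitope_index=ex_ne, manifest=manifest)
        except Exception as exc:
            raise RuntimeError(f"featurization failed for fragment {i} "
                               f"({frag.source_id}): {exc}") from exc
        rows.append(vec.values)
    return np.vstack(rows)


def write_feature_matrix(matrix: np.ndarray, labels: list[bool],
                         path: str, names: list[str] | None = None) -> None:
    """Export a feature matrix as TSV: named columns plus a trailing label."""
    names = list(names or FEATURE_NAMES)
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\tlabel\n")
        for row, lab in zip(matrix, labels):
            fh.write("\t".join(f"{v:.8g}" for v in row)
                     + f"\t{1 if lab else 0}\n")
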