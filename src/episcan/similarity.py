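"""Multi-mer similarity between peptide fragments.

The similarity of two 20-mers is the total number of identical substrings
(multi-mers) they share: the same single residues, the same 2-mers, 3-mers and
so on. Two counting semantics are supported:

* ``distinct`` (default): for each substring length, count the distinct
  substrings present in both peptides (set intersection), summed over lengths.
  Because strings of different lengths are never equal, this equals the size
  of the intersection of the two complete substring sets.
* ``positional``: count ordered position pairs (i, j, L) at which the length-L
  substrings starting at i in one peptide and j in the other are identical.

Both are symmetric. The top-k similarity features of a query against an
epitope/non-epitope fragment library are its k highest pairwise scores per
side, zero-padded when a side has fewer than k members, with the query's own
library entry excluded under cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np


def substring_set(peptide: str) -> frozenset[str]:
    """All distinct substrings of a peptide (every length, every offset)."""
    n = len(peptide)
    return frozenset(peptide[i:j]
                     for i in range(n) for j in range(i + 1, n + 1))


@lru_cache(maxsize=65536)
def _cached_substring_set(peptide: str) -> frozenset[str]:
    return substring_set(peptide)


def fragment_similarity(a: str, b: str, mode: str = "distinct") -> int:
    """Total count of identical multi-mers shared by two peptides."""
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    if mode == "distinct":
        return len(_cached_substring_set(a) & _cached_substring_set(b))
    if mode == "positional":
        score = 0
        la, lb = len(a), len(b)
        for i in range(la):
            for j in range(lb):
                L = 0
                while i + L < la and j + L < lb and a[i + L] == b[j + L]:
                    L += 1
                    score += 1  # every extension shares one more multi-mer
        return score
    raise ValueError(f"unknown similarity mode {mode!r}")


@dataclass
class FragmentLibrary:
    """Labeled 20-mer reference set for similarity featurization.

    ``provenance`` tags the library (e.g. a cross-validation fold id) so model
    artifacts can record which reference set their features were computed
    against.
    """

    epitopes: list[str]
    non_epitopes: list[str]
    provenance: str = ""
    _ep_sets: list[frozenset[str]] = field(default=None, repr=False)  # type: ignore[assignment]
    _ne_sets: list[frozenset[str]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for pep in self.epitopes + self.non_epitopes:
            if len(pep) != 20:
                raise ValueError(
                    f"library peptides must be 20-mers, got {len(pep)}")
        self._ep_sets = [substring_set(p) for p in self.epitopes]
        self._ne_sets = [substring_set(p) for p in self.non_epitopes]

    def fingerprint(self) -> str:
        """Stable content hash identifying the reference set."""
        import hashlib
        h = hashlib.sha256()
        for p in self.epitopes:
            h.update(b"E" + p.encode())
        for p in self.non_epitopes:
            h.update(b"N" + p.encode())
        return h.hexdigest()[:16]


def topk_similarity(query: str, library: FragmentLibrary, k: int = 5,
                    mode: str = "distinct",
                    exclude_epitope_index: int | None = None,
                    exclude_non_epitope_index: int | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """k highest similarity scores per library side, sorted descending.

    Sides with fewer than k members are zero-padded. ``exclude_*_index``
    drops one library entry by position — the cross-validation hygiene rule
    that a training fragment never matches its own library record (duplicate
    peptides at other positions still count).
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def side(peps: list[str], sets: list[frozenset[str]],
             skip: int | None) -> np.ndarray:
        if mode == "distinct":
            qset = _cached_substring_set(query)
            scores = [len(qset & s) for i, s in enumerate(sets) if i != skip]
        else:
            scores = [fragment_similarity(query, p, mode=mode)
                      for i, p in enumerate(peps) if i != skip]
        scores.sort(reverse=True)
        out = np.zeros(k)
        top = scores[:k]
        out[: len(top)] = top
        return out

    return (side(library.epitopes, library._ep_sets, exclude_epitope_index),
            side(library.non_epitopes, library._ne_sets,
                 exclude_non_epitope_index))
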