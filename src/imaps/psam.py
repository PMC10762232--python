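"""Position-specific affinity matrix (PSAM) scanning.

A PSAM gives, for each of k positions, the relative binding affinity of
the four bases, normalized so the ideal base at each position scores 1.0.
The affinity of a k-mer window is the product of its per-position entries,
so the ideal site scores exactly 1.0 and every other window a value in
[0, 1].  Scanning is 5'->3' on the given sense strand only: these are RNA
binding models, so no reverse-complement scan is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: column order of PSAM matrices
PSAM_ALPHABET = "ACGU"

_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGU"):
    _INDEX[ord(_b)] = _i
    _INDEX[ord(_b.lower())] = _i
_INDEX[ord("T")] = 3  # T and U are synonyms
_INDEX[ord("t")] = 3


class PSAMError(ValueError):
    pass


@dataclass(frozen=True)
class PSAM:
    """k x 4 relative-affinity matrix for one RNA-binding protein."""

    rbp: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise PSAMError("PSAM matrix must be k x 4")
        if np.any(m < 0) or np.any(m > 1):
            raise PSAMError("PSAM entries must lie in [0, 1]")
        if not np.allclose(m.max(axis=1), 1.0):
            raise PSAMError("each PSAM row's maximum must equal 1.0 (ideal base)")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def ideal_site(self) -> str:
        return "".join(PSAM_ALPHABET[j] for j in self.matrix.argmax(axis=1))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#rbp={self.rbp}\tk={self.k}\n")
            fh.write("A\tC\tG\tU\n")
            for row in self.matrix:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "PSAM":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#rbp="):
                raise PSAMError(f"{path}: missing '#rbp=<name>\\tk=<k>' header")
            fields = dict(kv.split("=") for kv in header.lstrip("#").split("\t"))
            rows = []
            for line in fh:
                line = line.strip()
                if not line or line[0].isalpha():
                    continue
                rows.append([float(v) for v in line.split("\t")])
        m = np.array(rows)
        if m.shape[0] != int(fields["k"]):
            raise PSAMError(f"{path}: header k={fields['k']} but {m.shape[0]} rows")
        return cls(fields["rbp"], m)


@dataclass
class AffinityProfile:
    """Per-window affinities along a sequence; windows with N are masked to 0."""

    affinities: np.ndarray
    mask: np.ndarray  # True where the window contained an ambiguous base

    def __len__(self) -> int:
        return len(self.affinities)


def encode(sequence: str) -> np.ndarray:
    """Sequence -> base indices (A,C,G,U/T = 0..3; anything else -1)."""
    return _INDEX[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def window_affinity(psam: PSAM, kmer: str) -> float:
    """Relative affinity of a single k-mer: product of per-position entries."""
    if len(kmer) != psam.k:
        raise PSAMError(f"k-mer length {len(kmer)} != PSAM width {psam.k}")
    idx = encode(kmer)
    if (idx < 0).any():
        raise PSAMError(f"ambiguous base in k-mer {kmer!r}")
    return float(np.prod(psam.matrix[np.arange(psam.k), idx]))


def scan(psam: PSAM, sequence: str) -> AffinityProfile:
    """Affinity of every k-window of ``sequence``, 5'->3' on the sense strand.

    Windows containing an ambiguous base score 0 and are flagged in the
    mask.  A sequence shorter than k yields an empty profile.
    """
    k = psam.k
    idx = encode(sequence)
    n_win = len(idx) - k + 1
    if n_win <= 0:
        return AffinityProfile(np.empty(0), np.empty(0, dtype=bool))
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    bad = (windows < 0).any(axis=1)
    safe = np.where(windows < 0, 0, windows)
    aff = np.prod(psam.matrix[np.arange(k)[None, :], safe], axis=1)
    aff[bad] = 0.0
    return AffinityProfile(aff, bad)


def _covering_window_sum(profile: np.ndarray, pos: int, k: int, seq_len: int) -> float:
    """Sum of affinities of the k windows covering sequence position ``pos``;
    windows truncated by the sequence ends are dropped, not padded."""
    lo = max(0, pos - k + 1)
    hi = min(seq_len - k, pos)
    if hi < lo:
        return 0.0
    return float(profile[lo : hi + 1].sum())


def variant_affinities(
    psam: PSAM,
    sequence: str,
    pos: int,
    derived_base: str,
    site_start: Optional[int] = None,
    site_end: Optional[int] = None,
    local_flank: int = 25,
) -> tuple[float, float, Optional[float]]:
    """Ancestral, derived and local affinity sums around a variant.

    ``sequence`` is the ancestral sense-strand sequence and ``pos`` the
    0-based variant position within it.  Ancestral/derived affinities sum
    the k windows overlapping the variant (k affinities for a width-k
    model), computed on the ancestral and derived sequence respectively.
    When a site interval [site_start, site_end) is given, the local
    affinity sums all windows fully inside the span from ``local_flank``
    bases upstream of the site to ``local_flank`` bases downstream,
    clipped at the sequence boundaries.
    """
    k = psam.k
    if not 0 <= pos < len(sequence):
        raise PSAMError("variant position outside the sequence")
    if min(pos, len(sequence) - 1 - pos) < k - 1:
        raise PSAMError(
            f"variant needs >= {k - 1} flanking bases on each side for the "
            "covering-window sum"
        )
    anc_profile = scan(psam, sequence).affinities
    derived_seq = sequence[:pos] + derived_base + sequence[pos + 1 :]
    der_profile = scan(psam, derived_seq).affinities
    anc = _covering_window_sum(anc_profile, pos, k, len(sequence))
    der = _covering_window_sum(der_profile, pos, k, len(sequence))
    local = None
    if site_start is not None and site_end is not None:
        lo = max(0, site_start - local_flank)
        hi = min(len(sequence), site_end + local_flank)
        w_lo, w_hi = lo, hi - k  # windows fully inside the clipped span
        if w_hi >= w_lo:
            local = float(anc_profile[w_lo : w_hi + 1].sum())
        else:
            local = 0.0
    return anc, der, local
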