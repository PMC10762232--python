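"""Genomic mutability contexts: sequence flank + methylation + epigenetic strata.

Mutability of a single-nucleotide variant depends strongly on its local
sequence context (most famously CpG transitions), on methylation at CpG
sites, and on chromatin features such as DNase hypersensitivity and
H3K9me3.  This module defines the canonical (strand-collapsed) context keys
used to stratify variants when calibrating expected singleton proportions,
from the dinucleotide level (one flanking base on each side of the variant)
up to the hexanucleotide level (five flanking bases per side).

Counting arithmetic at the parent (dinucleotide) level:
4 ancestral x 3 derived x 4 left x 4 right = 192 sequence contexts, which
strand-collapse into 96 reverse-complement classes; the 4 NCG>NTG CpG
transition classes each carry three methylation strata instead of one
(96 + 8 = 104), and the two binary chromatin axes multiply this to
104 x 2 x 2 = 416 parent contexts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: context level -> number of flanking bases used on each side of the variant
LEVELS = {"di": 1, "tri": 2, "tetra": 3, "penta": 4, "hexa": 5}
LEVEL_ORDER = ("di", "tri", "tetra", "penta", "hexa")

METH_BINS = ("none", "low", "medium", "high")


class ContextError(ValueError):
    """Malformed or inconsistent context description."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def meth_bin_from_mean(mean_methylation: float) -> str:
    """Bin a mean methylation percentage (0-100) into low/medium/high.

    High is > 60, medium is (20, 60], low is <= 20.
    """
    if mean_methylation > 60:
        return "high"
    if mean_methylation > 20:
        return "medium"
    return "low"


@dataclass(frozen=True)
class ContextKey:
    """A strand-collapsed mutability context.

    ``level`` names the flank depth (di=1 base per side ... hexa=5).
    ``change`` is the (ancestral, derived) base pair as read on one strand;
    keys are compared and stored in canonical form, the lexicographically
    smaller of the key and its reverse complement (change first, then
    flanks).  ``meth_bin`` is only meaningful for NCG>NTG CpG transitions;
    all other contexts carry ``"none"``.
    """

    level: str
    change: tuple[str, str]
    left: str
    right: str
    meth_bin: str = "none"
    dnase: bool = False
    h3k9me3: bool = False

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ContextError(f"unknown context level {self.level!r}")
        anc, der = self.change
        flank = LEVELS[self.level]
        if anc not in BASES or der not in BASES:
            raise ContextError(f"invalid base change {anc}>{der}")
        if anc == der:
            raise ContextError("ancestral and derived base are identical")
        if len(self.left) != flank or len(self.right) != flank:
            raise ContextError(
                f"level {self.level} requires {flank} flanking bases per side"
            )
        for b in self.left + self.right:
            if b not in BASES:
                raise ContextError(f"invalid flank base {b!r}")
        if self.meth_bin not in METH_BINS:
            raise ContextError(f"invalid methylation bin {self.meth_bin!r}")
        if self.meth_bin != "none" and not self.is_cpg_transition:
            raise ContextError(
                "methylation bins apply only to NCG>NTG CpG transitions"
            )

    # -- strand handling ---------------------------------------------------

    @property
    def is_cpg_transition(self) -> bool:
        """True for a C>T at a CpG on either strand (NCG>NTG class)."""
        anc, der = self.change
        return (anc == "C" and der == "T" and self.right[0] == "G") or (
            anc == "G" and der == "A" and self.left[-1] == "C"
        )

    def reverse_complement(self) -> "ContextKey":
        anc, der = self.change
        return replace(
            self,
            change=(anc.translate(_COMP), der.translate(_COMP)),
            left=revcomp(self.right),
            right=revcomp(self.left),
        )

    def _sort_tuple(self) -> tuple:
        return (*self.change, self.left, self.right)

    @property
    def is_canonical(self) -> bool:
        return self._sort_tuple() <= self.reverse_complement()._sort_tuple()

    def serialize(self) -> str:
        anc, der = self.change
        return (
            f"{self.left}[{anc}>{der}]{self.right}"
            f"|{self.meth_bin}|dnase={int(self.dnase)}|h3k9me3={int(self.h3k9me3)}"
        )

    def code(self) -> str:
        """Compact string form used as the calibration-table key."""
        anc, der = self.change
        return (
            f"{self.level}:{self.left}[{anc}>{der}]{self.right}"
            f"|{self.meth_bin}|{int(self.dnase)}{int(self.h3k9me3)}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def canonicalize(key: ContextKey) -> ContextKey:
    """Return the canonical member of the reverse-complement pair.

    The pairing is fixed-point-free: no context equals its own reverse
    complement because the central ancestral base always differs from its
    complement, so exactly one member of each pair is canonical.
    """
    rc = key.reverse_complement()
    return key if key._sort_tuple() <= rc._sort_tuple() else rc


def truncate(key: ContextKey, level: str) -> ContextKey:
    """Truncate a key's flanks to a shallower level and re-canonicalize."""
    flank = LEVELS[level]
    if flank > LEVELS[key.level]:
        raise ContextError(f"cannot truncate {key.level} to deeper level {level}")
    return canonicalize(
        replace(key, level=level, left=key.left[-flank:], right=key.right[:flank])
    )


def enumerate_sequence_contexts(level: str = "di") -> set[ContextKey]:
    """All canonical sequence-only contexts at ``level`` (96 at di)."""
    flank = LEVELS[level]
    out = set()
    for anc in BASES:
        for der in BASES:
            if der == anc:
                continue
            for left in itertools.product(BASES, repeat=flank):
                for right in itertools.product(BASES, repeat=flank):
                    out.add(
                        canonicalize(
                            ContextKey(level, (anc, der), "".join(left), "".join(right))
                        )
                    )
    return out


def enumerate_parent_contexts() -> set[ContextKey]:
    """Every canonical parent (dinucleotide-level) context: 416 keys.

    96 strand-collapsed sequence contexts, methylation strata (low, medium,
    high) replacing "none" for the 4 NCG>NTG classes, crossed with the two
    binary chromatin axes.
    """
    out = set()
    for seq_key in enumerate_sequence_contexts("di"):
        bins = ("low", "medium", "high") if seq_key.is_cpg_transition else ("none",)
        for meth in bins:
            for dnase in (False, True):
                for h3k in (False, True):
                    out.add(replace(seq_key, meth_bin=meth, dnase=dnase, h3k9me3=h3k))
    return out


def child_contexts(parent: ContextKey, level: str) -> set[ContextKey]:
    """All canonical descendants of ``parent`` at a deeper flank level.

    A child extends each flank outward by free bases; a parent therefore has
    4^(2*(L_child - L_parent)) children (65,536 at hexa from di).  Each
    child truncates back to the parent.
    """
    extra = LEVELS[level] - LEVELS[parent.level]
    if extra <= 0:
        raise ContextError(
            f"child level {level} must be deeper than parent level {parent.level}"
        )
    out = set()
    for lext in itertools.product(BASES, repeat=extra):
        for rext in itertools.product(BASES, repeat=extra):
            out.add(
                canonicalize(
                    replace(
                        parent,
                        level=level,
                        left="".join(lext) + parent.left,
                        right=parent.right + "".join(rext),
                    )
                )
            )
    return out


@dataclass(frozen=True)
class VariantContext:
    """The raw material for context assignment at any level.

    ``window11`` is the 11-mer of ancestral sequence centred on the variant
    (5 bases per side, forward reference strand); ``derived`` the derived
    allele on the same strand.  ``meth`` is the mean methylation percentage
    at the CpG position, if any.
    """

    variant_id: str
    window11: str
    derived: str
    meth: Optional[float] = None
    dnase: bool = False
    h3k9me3: bool = False

    def __post_init__(self):
        if len(self.window11) != 11:
            raise ContextError("context window must be exactly 11 bases")
        if self.derived not in BASES:
            raise ContextError(f"invalid derived allele {self.derived!r}")
        if self.window11[5] == self.derived:
            raise ContextError("derived allele equals the ancestral (centre) base")

    @property
    def ancestral(self) -> str:
        return self.window11[5]

    @property
    def is_cpg_transition(self) -> bool:
        w = self.window11
        return (w[5] == "C" and self.derived == "T" and w[6] == "G") or (
            w[5] == "G" and self.derived == "A" and w[4] == "C"
        )


def assign_context(variant: VariantContext, level: str) -> ContextKey:
    """Canonical context key of a variant at the requested flank depth.

    Strand is handled solely through canonicalization: the window is read
    from the forward reference strand and the canonical form of the
    resulting key is returned.  The methylation bin propagates only for
    CpG transitions (C>T at CpG on either strand); methylation data at any
    other site is ignored.
    """
    flank = LEVELS[level]
    w = variant.window11
    left = w[5 - flank : 5]
    right = w[6 : 6 + flank]
    for b in left + right + w[5]:
        if b not in BASES:
            raise ContextError(
                f"variant {variant.variant_id}: non-ACGT base in the "
                f"{level} context window (should be pre-filtered)"
            )
    if variant.is_cpg_transition:
        if variant.meth is None:
            raise ContextError(
                f"variant {variant.variant_id}: CpG transition without "
                "methylation data (should be pre-filtered)"
            )
        meth_bin = meth_bin_from_mean(variant.meth)
    else:
        meth_bin = "none"
    return canonicalize(
        ContextKey(
            level,
            (w[5], variant.derived),
            left,
            right,
            meth_bin=meth_bin,
            dnase=variant.dnase,
            h3k9me3=variant.h3k9me3,
        )
    )


def parse_code(code: str) -> ContextKey:
    """Inverse of :meth:`ContextKey.code`."""
    level, rest = code.split(":", 1)
    seq, meth_bin, flags = rest.split("|")
    left, changed = seq.split("[")
    change, right = changed.split("]")
    anc, der = change.split(">")
    return ContextKey(
        level,
        (anc, der),
        left,
        right,
        meth_bin=meth_bin,
        dnase=flags[0] == "1",
        h3k9me3=flags[1] == "1",
    )


# ---------------------------------------------------------------------------
# Vectorized assignment (calibration-scale cohorts)
# ---------------------------------------------------------------------------

_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_LUT[_a] = _b


def _to_byte_matrix(strings: Sequence[str], width: int) -> np.ndarray:
    arr = np.asarray(strings, dtype=f"S{width}")
    return arr.view(np.uint8).reshape(len(arr), width)


def assign_context_codes(
    windows: Sequence[str],
    derived: Sequence[str],
    meth: Sequence[float],
    dnase: Sequence[bool],
    h3k9me3: Sequence[bool],
    level: str,
) -> np.ndarray:
    """Canonical context codes for many variants at once.

    Equivalent to ``assign_context(...).code()`` per variant but vectorized
    over byte matrices; used to stratify calibration-scale cohorts.
    ``meth`` is the mean methylation percentage with NaN for sites without
    data; it is consulted only at CpG transitions, where missing data is an
    error (such variants are filtered upstream).
    """
    flank = LEVELS[level]
    n = len(windows)
    if n == 0:
        return np.empty(0, dtype=object)
    W = _to_byte_matrix(windows, 11)
    der = _to_byte_matrix(derived, 1)[:, 0]
    anc = W[:, 5]
    ok = np.zeros(256, dtype=bool)
    ok[list(b"ACGT")] = True
    used = np.concatenate([W[:, 5 - flank : 5], anc[:, None], W[:, 6 : 6 + flank]], axis=1)
    if not ok[used].all() or not ok[der].all():
        raise ContextError("non-ACGT base inside the context window (pre-filter first)")
    cpg = ((anc == ord("C")) & (der == ord("T")) & (W[:, 6] == ord("G"))) | (
        (anc == ord("G")) & (der == ord("A")) & (W[:, 4] == ord("C"))
    )
    meth = np.asarray(meth, dtype=float)
    if np.isnan(meth[cpg]).any():
        raise ContextError("CpG transition without methylation data (pre-filter first)")
    meth_bin = np.full(n, "none", dtype=object)
    meth_bin[cpg & (meth <= 20)] = "low"
    meth_bin[cpg & (meth > 20) & (meth <= 60)] = "medium"
    meth_bin[cpg & (meth > 60)] = "high"

    left = W[:, 5 - flank : 5]
    right = W[:, 6 : 6 + flank]
    anc_c = _COMP_LUT[anc]
    der_c = _COMP_LUT[der]
    left_rc = _COMP_LUT[right][:, ::-1]
    right_rc = _COMP_LUT[left][:, ::-1]

    fwd = np.ascontiguousarray(
        np.concatenate([anc[:, None], der[:, None], left, right], axis=1)
    )
    rev = np.ascontiguousarray(
        np.concatenate([anc_c[:, None], der_c[:, None], left_rc, right_rc], axis=1)
    )
    width = 2 + 2 * flank
    fv = fwd.view(f"S{width}").ravel()
    rv = rev.view(f"S{width}").ravel()
    use_fwd = fv <= rv
    chosen = np.where(use_fwd[:, None], fwd, rev)

    anc_s = chosen[:, 0:1].copy().view("S1").ravel().astype("U1")
    der_s = chosen[:, 1:2].copy().view("S1").ravel().astype("U1")
    left_s = np.ascontiguousarray(chosen[:, 2 : 2 + flank]).view(f"S{flank}").ravel().astype(f"U{flank}")
    right_s = np.ascontiguousarray(chosen[:, 2 + flank :]).view(f"S{flank}").ravel().astype(f"U{flank}")

    d_flag = np.where(np.asarray(dnase, dtype=bool), "1", "0")
    h_flag = np.where(np.asarray(h3k9me3, dtype=bool), "1", "0")
    prefix = f"{level}:"
    codes = np.char.add(
        np.char.add(
            np.char.add(np.char.add(prefix, left_s), np.char.add("[", anc_s)),
            np.char.add(np.char.add(">", der_s), np.char.add("]", right_s)),
        ),
        np.char.add(
            np.char.add("|", meth_bin.astype("U6")),
            np.char.add("|", np.char.add(d_flag, h_flag)),
        ),
    )
    return codes.astype(object)
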