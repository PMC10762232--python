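"""Intergenic proportion-singleton calibration with extended-context selection.

The calibrator is fit on filtered, annotated intergenic variants.  It
records the proportion of singletons per parent (dinucleotide-level)
context as the mutability baseline, then iterates from hexanucleotide down
to trinucleotide flank depth, testing each extended context against its
parent with a two-sided Fisher exact test and accepting contexts whose
singleton proportion differs at a Benjamini-Hochberg FDR of 0.2.  Variants
under an accepted deeper context do not re-enter testing at shallower
levels.  Query variants are assigned the proportion singleton of the
deepest accepted ancestor context, defaulting to the parent.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import contexts
from .stats import fisher_two_sided

EXTENDED_LEVELS = ("hexa", "penta", "tetra", "tri")

#: columns a variant table must provide for calibration / scoring
VARIANT_COLUMNS = ("window11", "derived", "meth", "dnase", "h3k9me3")


class UncalibratedContextError(KeyError):
    """A query context has no parent entry in the calibration table."""


def _require_columns(X: pd.DataFrame, need_singleton: bool) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in X.columns]
    if need_singleton and "is_singleton" not in X.columns:
        missing.append("is_singleton")
    if missing:
        raise ValueError(f"variant table is missing columns: {missing}")


def _codes(X: pd.DataFrame, level: str) -> np.ndarray:
    meth = X["meth"] if "meth" in X.columns else np.full(len(X), np.nan)
    return contexts.assign_context_codes(
        X["window11"].to_numpy(),
        X["derived"].to_numpy(),
        np.asarray(meth, dtype=float),
        X["dnase"].to_numpy(),
        X["h3k9me3"].to_numpy(),
        level,
    )


class ContextCalibrator(BaseEstimator):
    """Expected proportion-singleton lookup calibrated on intergenic variants.

    Parameters
    ----------
    fdr : float
        Benjamini-Hochberg false discovery rate for accepting extended
        contexts (default 0.2).
    levels : tuple of str
        Extended levels evaluated, deepest first.
    exclude_child_from_parent : bool
        If True (default) the 2x2 exact test compares the child context to
        its parent *minus* the child, keeping the two cells disjoint.
    min_child_n : int
        Minimum variant count for an extended context to be tested.

    Attributes
    ----------
    parent_table_ : pandas.DataFrame
        One row per observed parent context: n, s, ps (indexed by code).
    extended_table_ : pandas.DataFrame
        Accepted extended contexts with level, n, s, ps, p, q.
    n_variants_ : int
        Number of intergenic variants used in the fit.
    """

    def __init__(
        self,
        fdr: float = 0.2,
        levels: Sequence[str] = EXTENDED_LEVELS,
        exclude_child_from_parent: bool = True,
        min_child_n: int = 1,
    ):
        self.fdr = fdr
        self.levels = tuple(levels)
        self.exclude_child_from_parent = exclude_child_from_parent
        self.min_child_n = min_child_n

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y: Optional[Sequence[bool]] = None):
        """Fit the calibration table on filtered intergenic variants.

        ``X`` must carry window11, derived, meth, dnase, h3k9me3 columns;
        the singleton indicator comes from ``y`` or an ``is_singleton``
        column.
        """
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        _require_columns(X, need_singleton=y is None)
        singleton = (
            np.asarray(y, dtype=bool) if y is not None else X["is_singleton"].to_numpy(bool)
        )
        if len(singleton) != len(X):
            raise ValueError("y length does not match X")
        if len(X) == 0:
            raise ValueError("cannot calibrate on an empty variant table")

        parent_codes = _codes(X, "di")
        parent = (
            pd.DataFrame({"code": parent_codes, "s": singleton.astype(int)})
            .groupby("code", sort=True)
            .agg(n=("s", "size"), s=("s", "sum"))
        )
        parent["ps"] = parent["s"] / parent["n"]
        self.parent_table_ = parent

        active = np.ones(len(X), dtype=bool)
        accepted_rows = []
        self._accepted_by_level_ = {}
        for level in self.levels:
            level_codes = _codes(X, level)
            idx = np.flatnonzero(active)
            if idx.size == 0:
                self._accepted_by_level_[level] = {}
                continue
            grp = (
                pd.DataFrame(
                    {
                        "code": level_codes[idx],
                        "parent": parent_codes[idx],
                        "s": singleton[idx].astype(int),
                    }
                )
                .groupby(["code", "parent"], sort=True)
                .agg(n=("s", "size"), s=("s", "sum"))
                .reset_index()
            )
            grp = grp[grp["n"] >= self.min_child_n]
            if grp.empty:
                self._accepted_by_level_[level] = {}
                continue
            pn = parent.loc[grp["parent"], "n"].to_numpy()
            ps_ = parent.loc[grp["parent"], "s"].to_numpy()
            a = grp["s"].to_numpy()
            b = grp["n"].to_numpy() - a
            if self.exclude_child_from_parent:
                c = ps_ - a
                d = (pn - ps_) - b
            else:
                c = ps_
                d = pn - ps_
            # a child can only outnumber its parent cell if exclusion was
            # disabled; clip never triggers in the default configuration
            c = np.maximum(c, 0)
            d = np.maximum(d, 0)
            pvals = fisher_two_sided(a, b, c, d)
            reject, qvals, _, _ = multipletests(pvals, alpha=self.fdr, method="fdr_bh")
            grp = grp.assign(ps=grp["s"] / grp["n"], p=pvals, q=qvals, level=level)
            acc = grp[reject]
            self._accepted_by_level_[level] = dict(zip(acc["code"], acc["ps"]))
            if not acc.empty:
                accepted_rows.append(acc)
                hit = pd.Series(level_codes[idx]).isin(set(acc["code"])).to_numpy()
                active[idx[hit]] = False

        if accepted_rows:
            ext = pd.concat(accepted_rows, ignore_index=True)
            self.extended_table_ = ext[["code", "parent", "level", "n", "s", "ps", "p", "q"]]
        else:
            self.extended_table_ = pd.DataFrame(
                columns=["code", "parent", "level", "n", "s", "ps", "p", "q"]
            )
        self.n_variants_ = int(len(X))
        return self

    # -- lookup ------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "parent_table_"):
            raise AttributeError("ContextCalibrator is not fitted")

    def predict(self, X: pd.DataFrame, return_level: bool = False):
        """Expected proportion singleton for each query variant.

        Resolution walks the accepted extended contexts deepest-first and
        falls back to the parent context.  A query whose parent context was
        never observed intergenic raises ``UncalibratedContextError``
        rather than silently defaulting.
        """
        ps, lvl, _ = self._resolve(X)
        if return_level:
            return ps, lvl
        return ps

    def predict_detail(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-variant expected ps with the resolved context code and level."""
        ps, lvl, code = self._resolve(X)
        return pd.DataFrame({"expected_ps": ps, "level": lvl, "code": code})

    def _resolve(self, X: pd.DataFrame):
        self._check_fitted()
        _require_columns(X, need_singleton=False)
        n = len(X)
        ps = np.full(n, np.nan)
        lvl = np.full(n, "", dtype=object)
        resolved_code = np.full(n, "", dtype=object)
        unresolved = np.ones(n, dtype=bool)
        for level in self.levels:
            table = self._accepted_by_level_.get(level, {})
            if not table or not unresolved.any():
                continue
            codes = _codes(X, level)
            hit = pd.Series(codes).map(table).to_numpy(dtype=float)
            take = unresolved & ~np.isnan(hit)
            ps[take] = hit[take]
            lvl[take] = level
            resolved_code[take] = codes[take]
            unresolved &= ~take
        if unresolved.any():
            codes = _codes(X.loc[unresolved], "di")
            parent_ps = self.parent_table_["ps"]
            hit = pd.Series(codes).map(parent_ps).to_numpy(dtype=float)
            if np.isnan(hit).any():
                bad = sorted(set(np.asarray(codes)[np.isnan(hit)]))
                raise UncalibratedContextError(
                    f"uncalibrated context(s): {bad[:5]}{'...' if len(bad) > 5 else ''}"
                )
            ps[unresolved] = hit
            lvl[unresolved] = "di"
            resolved_code[unresolved] = codes
        return ps, lvl, resolved_code

    def table_counts(self) -> pd.DataFrame:
        """n, s, ps per resolvable context code (parents + accepted extended)."""
        self._check_fitted()
        parent = self.parent_table_.reset_index()[["code", "n", "s", "ps"]]
        parts = [parent]
        if len(self.extended_table_):
            parts.append(self.extended_table_[["code", "n", "s", "ps"]])
        return pd.concat(parts, ignore_index=True).set_index("code")

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict(X)

    def resolution_summary(self, X: pd.DataFrame) -> pd.Series:
        """Fraction of query variants resolved at each context depth."""
        _, lvl = self.predict(X, return_level=True)
        return pd.Series(lvl).value_counts(normalize=True).sort_index()

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        self._check_fitted()
        parent = self.parent_table_.reset_index()
        parent["level"] = "di"
        parent["parent"] = parent["code"]
        parent["p"] = np.nan
        parent["q"] = np.nan
        cols = ["code", "parent", "level", "n", "s", "ps", "p", "q"]
        parts = [parent[cols]]
        if len(self.extended_table_):
            parts.append(self.extended_table_[cols])
        return pd.concat(parts, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **params) -> "ContextCalibrator":
        self = cls(**params)
        parent = frame[frame["level"] == "di"].set_index("code")[["n", "s", "ps"]]
        self.parent_table_ = parent
        ext = frame[frame["level"] != "di"].reset_index(drop=True)
        self.extended_table_ = ext
        self._accepted_by_level_ = {
            level: dict(zip(sub["code"], sub["ps"]))
            for level, sub in ext.groupby("level")
        }
        self.n_variants_ = int(parent["n"].sum())
        return self

    @classmethod
    def from_tsv(cls, path, **params) -> "ContextCalibrator":
        return cls.from_frame(pd.read_csv(path, sep="\t"), **params)


def build_parent_table(intergenic: pd.DataFrame, **params) -> ContextCalibrator:
    """Parent-level-only calibrator (no extended-context selection)."""
    cal = ContextCalibrator(levels=(), **params)
    return cal.fit(intergenic)


def select_extended_contexts(intergenic: pd.DataFrame, fdr: float = 0.2, **params) -> ContextCalibrator:
    """Full calibration: parent baselines plus FDR-selected extended contexts."""
    return ContextCalibrator(fdr=fdr, **params).fit(intergenic)


def expected_ps(calibrator: ContextCalibrator, X: pd.DataFrame) -> np.ndarray:
    """Expected proportion singleton per variant (thin wrapper on predict)."""
    return calibrator.predict(X)
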