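"""Mapping-marker discovery from the wildtype-sibling pool.

In an F2 incross every strain-diagnostic SNP segregates in the siblings, so
informative mapping markers are positions that look robustly heterozygous in
the wildtype pool: adequate read depth and an allele fraction away from 0 or
1. Markers are selected on wildtype-pool evidence alone; mutant-pool depth
is not required here (zero-depth markers are flagged downstream).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genome import NUCLEOTIDES

logger = logging.getLogger(__name__)

MARKER_COLUMNS = [
    "chrom", "pos", "ref", "alt", "mut_ref", "mut_alt", "wt_ref", "wt_alt",
]


class MarkerSelector(BaseEstimator, TransformerMixin):
    """Select high-quality mapping SNPs from a pooled marker count table.

    Parameters
    ----------
    min_depth : int, default 20
        Minimum wildtype-pool read depth (ref + alt).
    wt_af_min, wt_af_max : float, defaults 0.2 / 0.8
        Retained wildtype-pool alt-allele fraction window.
    min_mut_depth : int or None, default None
        Optional minimum mutant-pool depth; off by default (markers are
        selected on wildtype-pool criteria).

    After :meth:`transform`, ``rejection_tally_`` holds per-filter rejection
    counts in application order.
    """

    def __init__(self, min_depth: int = 20, wt_af_min: float = 0.2,
                 wt_af_max: float = 0.8, min_mut_depth: int | None = None):
        self.min_depth = min_depth
        self.wt_af_min = wt_af_min
        self.wt_af_max = wt_af_max
        self.min_mut_depth = min_mut_depth

    def _validate_params(self) -> None:
        if not 0 <= self.wt_af_min < self.wt_af_max <= 1:
            raise ValueError("need 0 <= wt_af_min < wt_af_max <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    def fit(self, X: pd.DataFrame, y=None) -> "MarkerSelector":
        self._validate_params()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._validate_params()
        missing = [c for c in MARKER_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"marker table missing columns {missing}")
        keep = np.ones(len(X), dtype=bool)
        tally: dict[str, int] = {}

        snv = (
            X["ref"].astype(str).isin(NUCLEOTIDES)
            & X["alt"].astype(str).isin(NUCLEOTIDES)
            & (X["ref"].astype(str) != X["alt"].astype(str))
        ).to_numpy()
        tally["not_biallelic_snv"] = int((keep & ~snv).sum())
        keep &= snv

        wt_depth = (X["wt_ref"] + X["wt_alt"]).to_numpy()
        deep = wt_depth >= self.min_depth
        tally["low_wt_depth"] = int((keep & ~deep).sum())
        keep &= deep

        with np.errstate(invalid="ignore", divide="ignore"):
            wt_af = np.where(wt_depth > 0, X["wt_alt"].to_numpy() / wt_depth, np.nan)
        in_window = (wt_af >= self.wt_af_min) & (wt_af <= self.wt_af_max)
        tally["wt_af_outside_window"] = int((keep & ~in_window).sum())
        keep &= in_window

        if self.min_mut_depth is not None:
            mut_depth = (X["mut_ref"] + X["mut_alt"]).to_numpy()
            ok = mut_depth >= self.min_mut_depth
            tally["low_mut_depth"] = int((keep & ~ok).sum())
            keep &= ok

        self.rejection_tally_ = tally
        self.n_retained_ = int(keep.sum())
        out = X.loc[keep].copy()
        for name, n in tally.items():
            logger.info("marker filter %s: rejected %d", name, n)
        if out.empty:
            logger.warning("no markers passed the filters")
            out.attrs["status"] = "no_markers"
        else:
            out.attrs["status"] = "ok"
        out.attrs["marker_filter"] = self.get_params()
        return out


def select_mapping_markers(
    table: pd.DataFrame,
    min_depth: int = 20,
    wt_af_min: float = 0.2,
    wt_af_max: float = 0.8,
    min_mut_depth: int | None = None,
) -> pd.DataFrame:
    """Functional wrapper around :class:`MarkerSelector`.

    Returns the retained subset (row order preserved); ``.attrs["status"]``
    is ``"no_markers"`` when nothing survives, never an exception.
    """
    sel = MarkerSelector(min_depth=min_depth, wt_af_min=wt_af_min,
                         wt_af_max=wt_af_max, min_mut_depth=min_mut_depth)
    return sel.fit(table).transform(table)
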