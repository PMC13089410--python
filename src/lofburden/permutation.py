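"""Frequency-preserving permutation null and rank statistics.

Each of 101 permutation replicates shuffles every burden column
independently across accessions, preserving the column's allele frequency
exactly.  Scans of the first 100 permuted matrices provide, per
(marker, phenotype) pair, an empirical distribution against which the
observed p-value is ranked (rank 1 = observed beats every permutation).
Ranking the 101st permutation against the first 100 gives a matched null
rank distribution that is uniform on {1..101} by exchangeability.
"""
from __future__ import annotations

from typing import Callable, Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

N_PERMS_DEFAULT = 101


def _column_rng(seed: int, perm_index: int, column_index: int) -> np.random.Generator:
    """Counter-style stream: any (permutation, column) reproducible alone."""
    return np.random.default_rng(np.random.SeedSequence([seed, perm_index, column_index]))


def permute_matrix(matrix: pd.DataFrame, perm_index: int, seed: int) -> pd.DataFrame:
    """Shuffle each column independently; column sums are preserved exactly."""
    n = matrix.shape[0]
    out = np.empty(matrix.shape, dtype=matrix.to_numpy().dtype)
    arr = matrix.to_numpy()
    for j in range(matrix.shape[1]):
        rng = _column_rng(seed, perm_index, j)
        out[:, j] = arr[rng.permutation(n), j]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rank_observed(p_obs: np.ndarray, p_sims: np.ndarray) -> np.ndarray:
    """Rank of the observed statistic among permutation replicates.

    ``p_sims`` has shape (n_perms, ...) matching ``p_obs``.  The rank is
    1 + #{sims < obs} + #{sims == obs}: ties count against the observed
    value, so rank 1 means the observed p beats all permutations strictly.
    NaNs in the simulations are treated as worthless (infinitely large) p.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    p_sims = np.asarray(p_sims, dtype=float)
    if p_sims.shape[0] < 100:
        raise ValueError(f"need >= 100 permutation replicates, got {p_sims.shape[0]}")
    sims = np.where(np.isnan(p_sims), np.inf, p_sims)
    less = (sims < p_obs).sum(axis=0)
    equal = (sims == p_obs).sum(axis=0)
    return (1 + less + equal).astype(int)


def null_rank_matrix(p_extra: np.ndarray, p_sims: np.ndarray) -> np.ndarray:
    """Ranks of a held-out permutation among the other replicates.

    Applying the observed-rank rule to the final (e.g. 101st) permutation
    produces a null rank matrix whose distribution is uniform on
    {1..n_perms} under exchangeability.
    """
    return rank_observed(p_extra, p_sims)


def rank_enrichment(observed_ranks: np.ndarray, null_ranks: np.ndarray,
                    n_ranks: int = N_PERMS_DEFAULT) -> pd.DataFrame:
    """Per-rank ratio of observed to null rank frequencies (null expectation 1)."""
    obs = np.asarray(observed_ranks).ravel()
    nul = np.asarray(null_ranks).ravel()
    if nul.size == 0:
        raise ValueError("empty null rank set")
    if obs.size == 0:
        raise ValueError("empty observed rank set")
    ranks = np.arange(1, n_ranks + 1)
    f_obs = np.array([(obs == r).mean() for r in ranks])
    f_nul = np.array([(nul == r).mean() for r in ranks])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f_nul > 0, f_obs / f_nul, np.nan)
    return pd.DataFrame({"rank": ranks, "observed_frac": f_obs,
                         "null_frac": f_nul, "ratio": ratio})


class PermutationScan:
    """Run the full 101-permutation protocol against fitted scan results.

    Parameters
    ----------
    results : ScanResults from a fitted BurdenScan — its null variance
        components are reused for every permutation scan.
    n_perms : total permutation replicates (the last one is held out as
        the matched null; the default 101 ranks against 100).
    seed : master seed; per-(permutation, column) streams are derived so
        any single permutation is reproducible in isolation.
    """

    def __init__(self, results, n_perms: int = N_PERMS_DEFAULT, seed: int = 0):
        if n_perms < 101:
            raise ValueError("need at least 101 permutation replicates")
        self.results = results
        self.n_perms = n_perms
        self.seed = seed
        self._p_obs: Optional[pd.DataFrame] = None
        self.rank_frame: Optional[pd.DataFrame] = None

    def run(self, statistic: str = "p_value") -> "PermutationScan":
        """Scan all permuted matrices and compute observed + null ranks.

        ``statistic`` is ``"p_value"`` (smaller wins) or ``"abs_beta"``
        (larger wins; internally negated so the same rank rule applies).
        """
        res = self.results
        markers = res.model.markers

        def stat_of(frame: pd.DataFrame) -> pd.DataFrame:
            wide_p = frame.pivot(index="marker", columns="phenotype", values="p_value")
            if statistic == "p_value":
                return wide_p
            wide_b = frame.pivot(index="marker", columns="phenotype", values="beta")
            return -wide_b.abs()

        obs = stat_of(res.frame).loc[markers.columns]
        sims = np.empty((self.n_perms,) + obs.shape)
        for k in range(self.n_perms):
            perm = permute_matrix(markers, perm_index=k + 1, seed=self.seed)
            frame = res.scan_permuted(perm)
            sims[k] = stat_of(frame).loc[markers.columns].to_numpy()
        self._p_obs = obs
        obs_rank = rank_observed(obs.to_numpy(), sims[: self.n_perms - 1])
        nul_rank = null_rank_matrix(sims[self.n_perms - 1], sims[: self.n_perms - 1])
        rows = []
        for i, m in enumerate(obs.index):
            for j, ph in enumerate(obs.columns):
                rows.append((m, ph, int(obs_rank[i, j]), int(nul_rank[i, j])))
        self.rank_frame = pd.DataFrame(
            rows, columns=["marker", "phenotype", "rank", "null_rank"]
        )
        return self

    def enrichment(self) -> pd.DataFrame:
        if self.rank_frame is None:
            raise RuntimeError("call run() first")
        return rank_enrichment(self.rank_frame["rank"].to_numpy(),
                               self.rank_frame["null_rank"].to_numpy(),
                               n_ranks=self.n_perms)

    def to_tsv(self, path: str) -> None:
        if self.rank_frame is None:
            raise RuntimeError("call run() first")
        self.rank_frame.to_csv(path, sep="\t", index=False)
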