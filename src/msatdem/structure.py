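"""Post-processing of external Bayesian clustering runs.

The clustering MCMC itself (admixture / linkage models) is out of scope;
this module consumes its outputs: per-run log probabilities of the data
for a range of cluster numbers K (for the Evanno second-difference
statistic ΔK) and per-run membership matrices (for label alignment
across runs, the computational core of CLUMPP-style averaging).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd


def read_likelihood_table(path) -> pd.DataFrame:
    """TSV with columns ``K  run  lnP``."""
    df = pd.read_csv(path, sep="\t")
    if not {"K", "run", "lnP"}.issubset(df.columns):
        raise ValueError("likelihood table needs columns K, run, lnP")
    return df


@dataclass
class DeltaKResult:
    delta_k: dict[int, float]
    undefined: list[int]  # interior Ks with zero run-to-run sd

    @property
    def best_k(self) -> int:
        return max(self.delta_k, key=self.delta_k.get)


def delta_k(table: pd.DataFrame) -> DeltaKResult:
    """Evanno ΔK from a ``K / run / lnP`` table.

    ΔK(K) = |mean lnP(K+1) - 2 mean lnP(K) + mean lnP(K-1)| / sd(lnP(K)),
    with the sample (n-1) standard deviation across runs.  Endpoint Ks
    have no ΔK; a K with zero sd is reported undefined.
    """
    ks = sorted(table["K"].unique())
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be contiguous")
    means, sds = {}, {}
    for k in ks:
        vals = table.loc[table["K"] == k, "lnP"].to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"need >= 2 runs per K (K={k} has {len(vals)})")
        means[k] = vals.mean()
        sds[k] = vals.std(ddof=1)
    out: dict[int, float] = {}
    undefined: list[int] = []
    for k in ks[1:-1]:
        second = abs(means[k + 1] - 2 * means[k] + means[k - 1])
        if sds[k] == 0:
            undefined.append(k)
        else:
            out[k] = second / sds[k]
    return DeltaKResult(out, undefined)


def align_runs(
    runs: list[np.ndarray], max_exhaustive_k: int = 8, greedy: bool = False
) -> list[np.ndarray]:
    """Align cluster labels across runs of equal K.

    For each run the column permutation maximising the summed
    per-individual dot product with the first run is applied (exhaustive
    over K! permutations for K <= ``max_exhaustive_k``).  Rows are never
    changed, only column order.
    """
    if not runs:
        return []
    mats = [np.asarray(r, float) for r in runs]
    k = mats[0].shape[1]
    for m in mats:
        if m.shape != mats[0].shape:
            raise ValueError("all runs must share shape (individuals x K)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("membership rows must sum to 1")
    if k > max_exhaustive_k and not greedy:
        raise ValueError(
            f"K={k} exceeds exhaustive limit {max_exhaustive_k}; pass greedy=True"
        )
    ref = mats[0]
    out = [ref.copy()]
    for m in mats[1:]:
        score = ref.T @ m  # score[i, j] = gain of mapping column j -> i
        if greedy and k > max_exhaustive_k:
            perm = _greedy_assignment(score)
        else:
            best, best_val = None, -np.inf
            for p in iter_permutations(range(k)):
                val = sum(score[i, p[i]] for i in range(k))
                if val > best_val:
                    best, best_val = p, val
            perm = np.array(best)
        out.append(m[:, perm])
    return out


def _greedy_assignment(score: np.ndarray) -> np.ndarray:
    k = score.shape[0]
    perm = np.full(k, -1)
    used = set()
    order = np.dstack(np.unravel_index(np.argsort(-score, axis=None), score.shape))[0]
    for i, j in order:
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return perm
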