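"""Approximate Bayesian computation for demographic scenario choice and
parameter estimation.

The reference table holds, for each simulated dataset, its generating
scenario, parameter draw and a summary-statistic vector.  Statistics are
standardised by their median absolute deviation across the table (sd
fallback when the MAD is zero) and compared to the observed vector by
Euclidean distance.

Scenario choice:

* *direct* estimate — the relative proportion of each scenario among the
  ``n_closest`` records;
* *logistic* estimate — a polychotomous logistic regression of scenario
  identity on the standardised differences between simulated and
  observed statistics over the retained records, weighted by an
  Epanechnikov kernel of relative distance; the prediction at zero
  difference (the intercept) is the point estimate.

Parameter estimation uses the accepted records of one scenario with a
local-linear regression adjustment on log-transformed parameters and
reports the weighted-kernel-density mode and 95% highest posterior
density interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression

from .coalsim import MutationModel, SampleConfig, simulate_dataset
from .demography import Scenario, sample_parameters
from .differentiation import wc_components_locus
from .genepop import MALE, Z_LINKED, Dataset

# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summary_labels(populations: Sequence[str]) -> list[str]:
    """Statistic order: per population (mean alleles, mean He, mean
    allele-size variance), then per pair (F_ST, (δμ)²)."""
    labels = []
    for p in populations:
        labels += [f"nal:{p}", f"he:{p}", f"var:{p}"]
    for p1, p2 in combinations(populations, 2):
        labels += [f"fst:{p1}|{p2}", f"dmu2:{p1}|{p2}"]
    return labels


def summarize_dataset(d: Dataset, populations: Sequence[str] | None = None) -> np.ndarray:
    """Summary-statistic vector for ABC (see :func:`summary_labels`).

    ``populations`` fixes the population order of the vector layout;
    records compared against each other (one reference table plus its
    observed vector) must share it.  Undefined entries (monomorphic pairs
    yield an undefined theta) are reported as 0 so that records remain
    comparable.
    """
    pops = list(populations) if populations is not None else d.populations
    missing = set(pops) - set(d.populations)
    if missing:
        raise ValueError(f"dataset lacks populations {sorted(missing)}")
    masks = {p: d.population_mask(p) for p in pops}
    male = d.sex_array() == MALE

    per_pop: dict[str, tuple[float, float, float]] = {}
    mean_sizes: dict[str, np.ndarray] = {}  # per locus mean allele size
    # typed diploid genotype blocks per population x locus (theta input;
    # male-only at Z-linked loci, matching the differentiation module)
    genos: dict[str, list[np.ndarray]] = {p: [] for p in pops}
    stats_acc = {p: ([], [], []) for p in pops}  # nal, he, var lists
    for j in range(d.n_loci):
        col = d.alleles[:, j, :]
        typed_dip = (col > 0).all(axis=1)
        if d.loci[j].inheritance == Z_LINKED:
            typed_dip = typed_dip & male
        for p in pops:
            m = masks[p]
            block = col[m]
            copies = block[block > 0]
            genos[p].append(col[m & typed_dip])
            nal, he, var = stats_acc[p]
            c = len(copies)
            if c == 0:
                continue
            _, counts = np.unique(copies, return_counts=True)
            nal.append(len(counts))
            freq = counts / c
            he.append(
                c / (c - 1) * (1.0 - float(np.sum(freq**2))) if c >= 2 else 0.0
            )
            if c >= 2:
                var.append(float(np.var(copies, ddof=1)))
            if p not in mean_sizes:
                mean_sizes[p] = np.full(d.n_loci, np.nan)
            mean_sizes[p][j] = copies.mean()
    for p in pops:
        nal, he, var = stats_acc[p]
        if not nal:
            raise ValueError(f"population {p!r} has no typed copies at any locus")
        per_pop[p] = (
            float(np.mean(nal)),
            float(np.mean(he)),
            float(np.mean(var)) if var else 0.0,
        )
        mean_sizes.setdefault(p, np.full(d.n_loci, np.nan))

    out: list[float] = []
    for p in pops:
        out.extend(per_pop[p])
    for p1, p2 in combinations(pops, 2):
        a_tot = abc_tot = 0.0
        for g1, g2 in zip(genos[p1], genos[p2]):
            a, b, c = wc_components_locus([g1, g2])
            a_tot += a
            abc_tot += a + b + c
        out.append(a_tot / abc_tot if abc_tot > 0 else 0.0)
        diff2 = (mean_sizes[p1] - mean_sizes[p2]) ** 2
        diff2 = diff2[~np.isnan(diff2)]
        out.append(float(diff2.mean()) if len(diff2) else 0.0)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary statistics) records."""

    scenario_ids: np.ndarray  # (n,) str
    params: pd.DataFrame  # (n, union of symbols), NaN where absent
    stats: np.ndarray  # (n, S)
    stat_labels: list[str]
    scenarios: list[str] = field(default_factory=list)  # distinct ids, order
    populations: list[str] = field(default_factory=list)  # summary layout order

    def summarize(self, d: Dataset) -> np.ndarray:
        """Observed summary vector in this table's statistic layout."""
        return summarize_dataset(d, self.populations or None)

    def __post_init__(self) -> None:
        if not self.scenarios:
            seen: dict[str, None] = {}
            for s in self.scenario_ids:
                seen.setdefault(str(s), None)
            self.scenarios = list(seen)

    def __len__(self) -> int:
        return len(self.scenario_ids)

    @property
    def scaling(self) -> np.ndarray:
        """Per-statistic robust scale: MAD, sd fallback, floor 1."""
        med = np.median(self.stats, axis=0)
        mad = np.median(np.abs(self.stats - med), axis=0)
        sd = self.stats.std(axis=0)
        scale = np.where(mad > 0, mad, sd)
        return np.where(scale > 0, scale, 1.0)

    def distances(self, observed: np.ndarray) -> np.ndarray:
        z = (self.stats - observed[None, :]) / self.scaling[None, :]
        return np.sqrt((z**2).sum(axis=1))


def _record_seed(seed: int, scenario_index: int, record_index: int) -> int:
    return int(
        np.random.SeedSequence([seed, scenario_index, record_index]).generate_state(1)[0]
    )


def build_reference_table(
    scenarios: Sequence[Scenario],
    n_per_scenario: int,
    config: SampleConfig,
    loci: Sequence,
    mut: MutationModel,
    seed: int,
    start: int = 0,
    stop: int | None = None,
) -> ReferenceTable:
    """Draw parameters, simulate and summarise ``n_per_scenario`` records
    per scenario.

    Record RNG streams are derived from (seed, scenario index, record
    index), so generating records in chunks (``start``/``stop``) and
    concatenating yields exactly the single-shot table.
    """
    stop = n_per_scenario if stop is None else min(stop, n_per_scenario)
    # canonical population order shared by every scenario's records
    pops = list(config.sizes)
    rows_params: list[dict[str, float]] = []
    rows_stats: list[np.ndarray] = []
    ids: list[str] = []
    for sidx, scenario in enumerate(scenarios):
        for i in range(start, stop):
            rec_seed = _record_seed(seed, sidx, i)
            draw = sample_parameters(scenario, 1, seed=rec_seed)[0]
            data = simulate_dataset(scenario, draw, config, loci, mut, rec_seed)
            rows_params.append(dict(draw.values))
            rows_stats.append(summarize_dataset(data, pops))
            ids.append(scenario.id)
    return ReferenceTable(
        scenario_ids=np.array(ids),
        params=pd.DataFrame(rows_params),
        stats=np.vstack(rows_stats),
        stat_labels=summary_labels(pops),
        scenarios=[s.id for s in scenarios],
        populations=pops,
    )


def concat_tables(tables: Sequence[ReferenceTable]) -> ReferenceTable:
    """Concatenate chunked tables (records interleaved back per scenario
    in generation order)."""
    if not tables:
        raise ValueError("no tables")
    labels = tables[0].stat_labels
    frames, stats, ids = [], [], []
    for t in tables:
        if t.stat_labels != labels:
            raise ValueError("tables have different statistic layouts")
        frames.append(t.params)
        stats.append(t.stats)
        ids.append(t.scenario_ids)
    order_ids = np.concatenate(ids)
    merged = ReferenceTable(
        scenario_ids=order_ids,
        params=pd.concat(frames, ignore_index=True),
        stats=np.vstack(stats),
        stat_labels=labels,
        scenarios=tables[0].scenarios,
        populations=tables[0].populations,
    )
    return merged


def save_reference_table(table: ReferenceTable, path: str | Path) -> None:
    """Persist as TSV with a small ``#``-prefixed manifest header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# msatdem reference table\n")
        fh.write("# stat_labels\t" + "\t".join(table.stat_labels) + "\n")
        fh.write("# scenarios\t" + "\t".join(table.scenarios) + "\n")
        fh.write("# populations\t" + "\t".join(table.populations) + "\n")
        df = table.params.copy()
        df.insert(0, "scenario", table.scenario_ids)
        for k, lab in enumerate(table.stat_labels):
            df[f"S{k}"] = table.stats[:, k]
        df.to_csv(fh, sep="\t", index=False)


def load_reference_table(path: str | Path) -> ReferenceTable:
    path = Path(path)
    stat_labels: list[str] = []
    scenarios: list[str] = []
    populations: list[str] = []
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            parts = line[1:].strip().split("\t")
            if parts[0] == "stat_labels":
                stat_labels = parts[1:]
            elif parts[0] == "scenarios":
                scenarios = parts[1:]
            elif parts[0] == "populations":
                populations = parts[1:]
    df = pd.read_csv(path, sep="\t", comment="#")
    stat_cols = [f"S{k}" for k in range(len(stat_labels))]
    return ReferenceTable(
        scenario_ids=df["scenario"].to_numpy(str),
        params=df.drop(columns=["scenario"] + stat_cols),
        stats=df[stat_cols].to_numpy(float),
        stat_labels=stat_labels,
        scenarios=scenarios,
        populations=populations,
    )


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    direct_probability: dict[str, float] | None
    logistic_probability: dict[str, float] | None
    n_closest: int | None = None
    n_regression: int | None = None

    @property
    def best(self) -> str:
        probs = self.logistic_probability or self.direct_probability
        return max(probs, key=probs.get)


def model_choice_direct(
    table: ReferenceTable, observed: np.ndarray, n_closest: int = 500
) -> ModelChoiceResult:
    """Scenario proportions among the ``n_closest`` records (Euclidean
    distance on MAD-standardised statistics; cutoff ties broken by record
    index)."""
    if n_closest > len(table):
        raise ValueError("n_closest exceeds table size")
    d = table.distances(observed)
    closest = np.argsort(d, kind="stable")[:n_closest]
    ids = table.scenario_ids[closest]
    probs = {s: float(np.mean(ids == s)) for s in table.scenarios}
    return ModelChoiceResult(direct_probability=probs, logistic_probability=None,
                             n_closest=n_closest)


def model_choice_logistic(
    table: ReferenceTable,
    observed: np.ndarray,
    n_regression: int,
    ridge: float = 1e-6,
) -> ModelChoiceResult:
    """Weighted polychotomous logistic regression point estimate.

    Retains the ``n_regression`` closest records, regresses scenario
    identity on the standardised statistic differences with Epanechnikov
    weights, and evaluates the fitted probabilities at zero difference.
    A small ridge penalty keeps separable configurations finite.
    """
    if n_regression > len(table):
        raise ValueError("n_regression exceeds table size")
    d = table.distances(observed)
    keep = np.argsort(d, kind="stable")[:n_regression]
    z = (table.stats[keep] - observed[None, :]) / table.scaling[None, :]
    y = table.scenario_ids[keep]
    present = [s for s in table.scenarios if (y == s).any()]
    absent = [s for s in table.scenarios if s not in present]
    for s in absent:
        warnings.warn(f"scenario {s!r} absent from the {n_regression} retained records")
    if len(present) < 2:
        probs = {s: (1.0 if s in present else 0.0) for s in table.scenarios}
        return ModelChoiceResult(None, probs, n_regression=n_regression)
    dmax = d[keep].max()
    w = 1.0 - (d[keep] / dmax) ** 2 if dmax > 0 else np.ones(len(keep))
    w = np.maximum(w, 1e-12)
    model = LogisticRegression(C=1.0 / ridge, max_iter=2000)
    model.fit(z, y, sample_weight=w)
    at_zero = model.predict_proba(np.zeros((1, z.shape[1])))[0]
    fitted = dict(zip(model.classes_, at_zero))
    probs = {s: float(fitted.get(s, 0.0)) for s in table.scenarios}
    total = sum(probs.values())
    probs = {s: p / total for s, p in probs.items()}
    return ModelChoiceResult(None, probs, n_regression=n_regression)


# ---------------------------------------------------------------------------
# parameter posteriors
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    mode: float
    hpd_low: float
    hpd_high: float
    samples: np.ndarray  # adjusted draws, natural units
    weights: np.ndarray


@dataclass
class ParameterPosterior:
    scenario: str
    parameters: dict[str, PosteriorSummary]
    n_accept: int


def _weighted_mode_hpd(
    values: np.ndarray,
    weights: np.ndarray,
    support: tuple[float, float],
    mass: float = 0.95,
    grid_size: int = 512,
) -> tuple[float, float, float]:
    """Mode and HPD of a weighted sample via Gaussian KDE on a grid.

    ``values`` are on the (possibly log) working scale; ``support`` is
    the prior support on that scale, used for clamping.
    """
    lo_s, hi_s = support
    if np.ptp(values) < 1e-12:
        v = float(np.clip(values[0], lo_s, hi_s))
        return v, v, v
    w = weights / weights.sum()
    kde = gaussian_kde(values, weights=w, bw_method="silverman")
    lo = max(lo_s, values.min() - 3 * np.sqrt(kde.covariance[0, 0]))
    hi = min(hi_s, values.max() + 3 * np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    mode = float(grid[np.argmax(dens)])
    order = np.argsort(dens)[::-1]
    total = dens.sum()
    cum = np.cumsum(dens[order]) / total
    k = int(np.searchsorted(cum, mass)) + 1
    region = grid[np.sort(order[:k])]
    return mode, float(region.min()), float(region.max())


def parameter_posterior(
    table: ReferenceTable,
    observed: np.ndarray,
    scenario: Scenario,
    n_accept: int = 500,
    adjust: bool = True,
    grid_size: int = 512,
) -> ParameterPosterior:
    """Regression-adjusted ABC posterior for one scenario's parameters.

    The ``n_accept`` closest records of that scenario are kept with
    Epanechnikov weights; each (strictly positive) parameter is
    log-transformed, adjusted by a weighted local-linear regression on
    the standardised statistic differences, and summarised by its
    weighted-KDE mode and 95% HPD interval, clamped to the prior support.
    ``adjust=False`` skips the regression (a plain weighted sample).
    """
    mask = table.scenario_ids == scenario.id
    if not mask.any():
        raise ValueError(f"scenario {scenario.id!r} not present in the table")
    idx = np.flatnonzero(mask)
    if n_accept > len(idx):
        raise ValueError(
            f"n_accept={n_accept} exceeds {len(idx)} records of scenario {scenario.id}"
        )
    d = table.distances(observed)[idx]
    order = np.argsort(d, kind="stable")[:n_accept]
    accepted = idx[order]
    d_acc = d[order]
    dmax = d_acc.max()
    w = 1.0 - (d_acc / dmax) ** 2 if dmax > 0 else np.ones(len(accepted))
    w = np.maximum(w, 1e-12)
    z = (table.stats[accepted] - observed[None, :]) / table.scaling[None, :]

    out: dict[str, PosteriorSummary] = {}
    for prior in scenario.priors:
        theta = table.params.loc[:, prior.name].to_numpy(float)[accepted]
        log_scale = prior.low > 0
        work = np.log(theta) if log_scale else theta.copy()
        if adjust and np.ptp(work) > 1e-12:
            # weighted local-linear regression: theta ~ 1 + z
            X = np.hstack([np.ones((len(z), 1)), z])
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], work * sw, rcond=None)
            work = work - z @ beta[1:]
        support = (
            (np.log(prior.low), np.log(prior.high))
            if log_scale
            else (prior.low, prior.high)
        )
        mode, lo, hi = _weighted_mode_hpd(work, w, support, grid_size=grid_size)
        work_cl = np.clip(work, *support)
        if log_scale:
            samples = np.exp(work_cl)
            mode, lo, hi = float(np.exp(mode)), float(np.exp(lo)), float(np.exp(hi))
        else:
            samples = work_cl
        # guard against round-trip floating error at the prior bounds
        samples = np.clip(samples, prior.low, prior.high)
        mode, lo, hi = (float(np.clip(v, prior.low, prior.high)) for v in (mode, lo, hi))
        out[prior.name] = PosteriorSummary(mode, lo, hi, samples, w.copy())
    return ParameterPosterior(scenario.id, out, n_accept)
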