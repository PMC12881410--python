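"""Synthetic autotetraploid cohorts with a known causal architecture.

The generator emulates a diversity panel of ~500 clonally replicated
genotypes scored on ~2,000 allele-dosage markers (values 0-4): admixed
subpopulation structure, LD blocks of correlated ancestral frequencies, and
a quantitative trait driven by a small set of direct-parent markers, a pair
of upstream hub markers acting through shared mediators, and an ancestry
confounder.  The planted structure is returned as an explicit ground-truth
DAG so every downstream stage (screening, graph learning, role
classification) can be scored against it.

Identifiability note: a hub with a single private mediator produces a
hub-mediator edge that is reversible within the Markov equivalence class,
so no constraint-based learner could ever orient it.  Hubs here therefore
co-regulate a *shared* mediator set; the resulting colliders
(hub1 -> mediator <- hub2) make the hub out-edges identifiable while each
hub still reaches the trait only through mediators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAIT_NODE = "trait"

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimCohort",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_cohort",
    "simulate_plot_trial",
]


@dataclass
class SimConfig:
    """Study-design parameters for a simulated cohort.

    Defaults mirror the data regime the pipeline targets: n=500 genotypes,
    2,000 post-design markers, two admixed subpopulations, five direct
    parents and two hubs jointly driving two shared mediators, trait noise
    SD 1.  Planted effect sizes are calibrated so a single screening
    repetition detects each carrier with probability near 0.9 at the
    stability threshold.
    """

    n_individuals: int = 500
    n_markers: int = 2000
    n_subpops: int = 2
    admixture_conc: float = 0.5
    ld_block_size: int = 10
    ld_copy_prob: float = 0.6
    n_direct_parents: int = 5
    n_hubs: int = 2
    mediators_per_hub: int = 2
    beta_parent: float = 0.55
    beta_confounder: float = 1.0
    hub_transfer: float = 0.85
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    diff_fraction: float = 0.5
    freq_jitter_sd: float = 0.02
    mediators_are_parents: bool = True
    trait_name: str = TRAIT_NODE
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_markers, self.n_subpops) <= 0:
            raise ValueError("n_individuals, n_markers and n_subpops must be positive")
        for name in ("n_direct_parents", "n_hubs", "mediators_per_hub", "ld_block_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        planted = self.n_direct_parents + self.n_hubs * (1 + self.mediators_per_hub)
        if planted > self.n_markers:
            raise ValueError("planted architecture larger than the marker panel")
        for name in ("ld_copy_prob", "missing_rate", "diff_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.hub_transfer < 1.0:
            raise ValueError("hub_transfer must lie in [0, 1)")
        if self.admixture_conc <= 0:
            raise ValueError("admixture_conc must be positive")


@dataclass
class SimTruth:
    """Planted causal ground truth of a simulated cohort."""

    parent_ids: list[str]
    hub_ids: list[str]
    mediator_map: dict[str, list[str]]
    trait_dag: list[tuple[str, str]]
    subpop_labels: np.ndarray
    effects: dict[str, float]
    trait_name: str = TRAIT_NODE

    @property
    def trait_parents(self) -> list[str]:
        """All markers with a direct edge into the trait (parents + mediators
        when mediators transmit the hub signal)."""
        return sorted({u for u, v in self.trait_dag if v == self.trait_name})

    def validate(self) -> None:
        if any(u == self.trait_name for u, _ in self.trait_dag):
            raise AssertionError("trait node must have out-degree 0")
        direct = {u for u, v in self.trait_dag if v == self.trait_name}
        if not set(self.parent_ids) <= direct:
            raise AssertionError("every parent must have a direct edge to the trait")
        if set(self.hub_ids) & direct:
            raise AssertionError("hubs may reach the trait only through mediators")


@dataclass
class SimCohort:
    dosages: pd.DataFrame
    phenotype: pd.Series
    truth: SimTruth
    ancestry: pd.DataFrame = field(repr=False, default=None)


def _marker_ids(n_markers: int, n_chrom: int = 8) -> list[str]:
    ids = []
    per = int(np.ceil(n_markers / n_chrom))
    for i in range(n_markers):
        chrom = i // per + 1
        pos = (i % per + 1) * 1000
        ids.append(f"chr{chrom}.1_{pos}")
    return ids


def simulate_genotypes(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an admixed dosage matrix.

    Per marker, each subpopulation receives an ancestral alternative-allele
    frequency Beta(0.5, 0.5) (independent across subpopulations for a
    ``diff_fraction`` share of "differentiated" markers, shared otherwise).
    Within LD blocks a marker copies its predecessor's frequencies with
    probability ``ld_copy_prob`` plus N(0, freq_jitter_sd) jitter.  Each
    individual draws ancestry weights from Dirichlet(admixture_conc) and a
    dosage Binomial(4, ancestry-weighted frequency).  Missing calls are MCAR
    at ``missing_rate``.

    Returns the dosage matrix (NaN where missing) and an ancestry table with
    one admixture-proportion column per subpopulation plus a hard ``label``
    column (argmax ancestry).
    """
    rng = np.random.default_rng(config.seed)
    n, m, s = config.n_individuals, config.n_markers, config.n_subpops

    shared = rng.beta(0.5, 0.5, size=m)
    diff = rng.beta(0.5, 0.5, size=(m, s))
    differentiated = rng.random(m) < config.diff_fraction
    freqs = np.where(differentiated[:, None], diff, shared[:, None])  # (m, s)

    block = config.ld_block_size
    if block > 1:
        copy = rng.random(m) < config.ld_copy_prob
        jitter = rng.normal(0.0, config.freq_jitter_sd, size=(m, s))
        for j in range(1, m):
            if j % block != 0 and copy[j]:
                freqs[j] = np.clip(freqs[j - 1] + jitter[j], 0.01, 0.99)
                differentiated[j] = differentiated[j - 1]

    weights = rng.dirichlet(np.full(s, config.admixture_conc), size=n)  # (n, s)
    p = weights @ freqs.T  # (n, m)
    dosages = rng.binomial(4, p).astype(float)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan

    individual_ids = [f"G{i + 1:04d}" for i in range(n)]
    dos = pd.DataFrame(dosages, index=pd.Index(individual_ids, name="individual_id"),
                       columns=_marker_ids(m))
    ancestry = pd.DataFrame(weights, index=dos.index,
                            columns=[f"pop{k}" for k in range(s)])
    ancestry["label"] = np.argmax(weights, axis=1)
    return dos, ancestry


def _pick_planted(dosages: pd.DataFrame, ancestry: pd.DataFrame, config: SimConfig,
                  rng: np.random.Generator) -> list[int]:
    """Column indices for planted causal markers.

    Candidates need a minor-dosage frequency in [0.3, 0.45] (a narrow band
    keeps the marker variances, and therefore the planted effect sizes on
    the standardised scale, near the prescribed detection power) and low
    alignment with the leading principal components of the marker matrix:
    markers riding on structure axes would have part of their causal signal
    removed by the PC adjustment and their hub-hub marginal independence
    -- required for collider orientation -- destroyed by shared ancestry.
    Chosen markers are spaced at least one LD block apart.
    """
    vals = dosages.to_numpy()
    col_mean = np.nanmean(vals, axis=0)
    p_hat = col_mean / 4.0
    maf = np.minimum(p_hat, 1 - p_hat)
    filled = np.where(np.isnan(vals), col_mean, vals)
    centred = filled - filled.mean(axis=0)
    sd = centred.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = centred / sd
    # R^2 of each marker on the top-10 PCs (computed here on the pre-trait
    # matrix; the downstream screen uses the same kind of adjustment)
    u, s, _ = np.linalg.svd(scaled, full_matrices=False)
    k = min(10, u.shape[1])
    proj = u[:, :k].T @ scaled  # (k, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc_r2 = (proj**2).sum(axis=0) / np.maximum((scaled**2).sum(axis=0), 1e-12)

    eligible = (maf >= 0.3) & (maf <= 0.45)
    if eligible.sum() > 0:
        cutoff = np.quantile(pc_r2[eligible], 0.2)
        preferred = eligible & (pc_r2 <= cutoff)
    else:
        preferred = np.ones(vals.shape[1], dtype=bool)

    n_needed = config.n_direct_parents + config.n_hubs + (
        config.mediators_per_hub if config.n_hubs > 0 else 0)
    chosen: list[int] = []
    for pool in (np.flatnonzero(preferred), np.flatnonzero(eligible),
                 np.arange(vals.shape[1])):
        for j in rng.permutation(pool):
            if len(chosen) == n_needed:
                break
            if all(abs(int(j) - c) >= config.ld_block_size for c in chosen):
                chosen.append(int(j))
        if len(chosen) == n_needed:
            break
    if len(chosen) < n_needed:
        raise RuntimeError("could not place the planted architecture")
    return chosen


def _rank_match(values: np.ndarray, latent: np.ndarray) -> np.ndarray:
    """Reorder ``values`` so its ranks follow ``latent`` (ties broken by
    latent order); the returned array is a permutation of ``values``."""
    order = np.argsort(latent, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    return np.sort(values)[ranks]


def simulate_trait(
    dosages: pd.DataFrame,
    ancestry: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.Series, SimTruth, pd.DataFrame]:
    """Plant the causal architecture and draw the trait.

    Mediator columns are regenerated as noisy monotone functions of the
    combined hub signal on a latent Gaussian scale
    (z = hub_transfer * s + sqrt(1 - hub_transfer^2) * eps) and mapped back
    to dosages by rank-matching against the original marginal, so the
    hub->mediator dependence is induced while each mediator's dosage
    multiset is preserved exactly.  The trait is
    y = sum_parents beta * dosage + beta_confounder * ancestry + N(0, noise_sd),
    with mediators contributing as parents when ``mediators_are_parents``.

    Returns (phenotype, truth, dosages-with-regenerated-mediators).
    """
    rng = np.random.default_rng((config.seed + 101) % 2**31)
    dosages = dosages.copy()
    cols = list(dosages.columns)

    planted = _pick_planted(dosages, ancestry, config, rng)
    n_med = config.mediators_per_hub if config.n_hubs > 0 else 0
    parent_idx = planted[: config.n_direct_parents]
    hub_idx = planted[config.n_direct_parents: config.n_direct_parents + config.n_hubs]
    med_idx = planted[config.n_direct_parents + config.n_hubs:
                      config.n_direct_parents + config.n_hubs + n_med]
    if len(set(parent_idx) | set(hub_idx) | set(med_idx)) != len(planted):
        raise RuntimeError("planted marker sets overlap")  # impossible by construction

    parent_ids = [cols[j] for j in parent_idx]
    hub_ids = [cols[j] for j in hub_idx]
    mediator_ids = [cols[j] for j in med_idx]

    def _filled(col: str) -> np.ndarray:
        v = dosages[col].to_numpy(copy=True)
        if np.isnan(v).any():
            v[np.isnan(v)] = np.nanmean(v)
        return v

    # hub -> mediator transfer on the latent scale
    if hub_ids and mediator_ids:
        hub_std = []
        for c in hub_ids:
            h = _filled(c)
            hub_std.append((h - h.mean()) / (h.std() or 1.0))
        signal = np.column_stack(hub_std).sum(axis=1) / np.sqrt(len(hub_ids))
        t = config.hub_transfer
        for med in mediator_ids:
            eps = rng.normal(size=len(dosages))
            latent = t * signal + np.sqrt(1.0 - t * t) * eps
            col = dosages[med].to_numpy(copy=True)
            observed = ~np.isnan(col)
            col[observed] = _rank_match(col[observed], latent[observed])
            dosages[med] = col

    trait_carriers = list(parent_ids)
    if config.mediators_are_parents:
        trait_carriers += mediator_ids

    effects: dict[str, float] = {}
    y = np.zeros(len(dosages))
    # mediators transmit with a common sign: opposite-signed mediator effects
    # would cancel along the shared hub signal and erase the hubs' total
    # effect on the trait
    mediator_sign = float(rng.choice([-1.0, 1.0]))
    for mid in trait_carriers:
        sign = mediator_sign if mid in mediator_ids else float(rng.choice([-1.0, 1.0]))
        beta = config.beta_parent * sign
        effects[mid] = beta
        y += beta * _filled(mid)

    anc_score = ancestry["pop0"].to_numpy()
    y = y + config.beta_confounder * anc_score + rng.normal(0.0, config.noise_sd,
                                                            size=len(dosages))

    trait_dag = [(p, config.trait_name) for p in parent_ids]
    trait_dag += [(h, m) for h in hub_ids for m in mediator_ids]
    if config.mediators_are_parents:
        trait_dag += [(m, config.trait_name) for m in mediator_ids]

    truth = SimTruth(
        parent_ids=parent_ids,
        hub_ids=hub_ids,
        mediator_map={h: list(mediator_ids) for h in hub_ids},
        trait_dag=trait_dag,
        subpop_labels=ancestry["label"].to_numpy(),
        effects=effects,
        trait_name=config.trait_name,
    )
    truth.validate()
    phenotype = pd.Series(y, index=dosages.index, name=config.trait_name)
    return phenotype, truth, dosages


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Full cohort draw: genotypes, planted trait and ground truth."""
    dosages, ancestry = simulate_genotypes(config)
    phenotype, truth, dosages = simulate_trait(dosages, ancestry, config)
    return SimCohort(dosages=dosages, phenotype=phenotype, truth=truth,
                     ancestry=ancestry)


def simulate_plot_trial(
    n_genotypes: int = 500,
    n_reps: int = 3,
    n_rows: int = 50,
    n_cols: int = 30,
    var_g: float = 1.0,
    var_row: float = 0.5,
    var_col: float = 0.5,
    var_e: float = 1.0,
    mu: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Field trial on a row x column grid with independent random genotype,
    row and column effects; used to exercise the spatial BLUP adjustment.

    Returns the plot table and the true genotype effects.
    """
    if n_genotypes * n_reps > n_rows * n_cols:
        raise ValueError("grid too small for the requested plots")
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(var_g), n_genotypes)
    r = rng.normal(0, np.sqrt(var_row), n_rows)
    c = rng.normal(0, np.sqrt(var_col), n_cols)
    cells = rng.permutation(n_rows * n_cols)[: n_genotypes * n_reps]
    geno = np.repeat(np.arange(n_genotypes), n_reps)
    rows = cells // n_cols
    cols = cells % n_cols
    y = mu + g[geno] + r[rows] + c[cols] + rng.normal(0, np.sqrt(var_e), len(cells))
    ids = [f"G{i + 1:04d}" for i in range(n_genotypes)]
    table = pd.DataFrame({
        "genotype_id": [ids[i] for i in geno],
        "replicate": np.tile(np.arange(1, n_reps + 1), n_genotypes),
        "row": rows,
        "column": cols,
        "value": y,
    })
    effects = pd.Series(g + mu, index=ids, name="true_effect")
    # realized variances of the drawn effects (finite level counts make
    # these the meaningful recovery targets, especially for rows/columns)
    effects.attrs["realized_variance"] = {
        "genotype": float(np.var(g, ddof=1)),
        "row": float(np.var(r, ddof=1)),
        "column": float(np.var(c, ddof=1)),
    }
    return table, effects
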