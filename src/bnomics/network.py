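"""Conditional Gaussian Bayesian network engine.

A conditional Gaussian Bayesian network (CGBN) is a DAG over discrete and
continuous nodes in which discrete nodes have multinomial conditional
probability tables and each continuous node follows, for every
configuration of its discrete parents, a linear Gaussian regression on its
continuous parents. Discrete nodes may not have continuous parents (the CG
restriction), which keeps the marginal likelihood of every family in
closed form:

* discrete child: Dirichlet–multinomial evidence with a low uniform
  Dirichlet prior (total pseudo-count mass ``alpha_total`` spread over the
  child's states, per parent configuration);
* continuous child: normal–inverse-gamma evidence (prior mean zero on
  standardized data, prior precision ``tau`` per coefficient, inverse-gamma
  shape ``a0`` and rate ``b0``), i.e. a multivariate-t marginal, summed
  over discrete-parent configurations.

Structure learning is an add-only greedy hill climb over single-edge
additions, repeated over bootstrap resamples of the subjects; the final
model is a consensus network assembled from bootstrap edge frequencies at
the threshold that maximizes cross-validated AUC for the phenotype, scored
through the phenotype's Markov neighborhood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "NodeSpec", "ScoreConfig", "BayesNetwork", "EdgeTally",
    "ConsensusSweepResult", "family_score_discrete",
    "family_score_continuous", "greedy_learn", "bootstrap_learn",
    "consensus_sweep", "markov_neighborhood", "fit_parameters",
    "predict_phenotype", "auc", "total_score",
]


@dataclass(frozen=True)
class NodeSpec:
    name: str
    kind: str  # "discrete" | "continuous"
    states: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == "discrete" and len(self.states) < 2:
            raise ValueError(f"discrete node {self.name!r} needs >= 2 states")


@dataclass(frozen=True)
class ScoreConfig:
    """Hyperparameters of the family marginal likelihoods."""

    dirichlet_alpha_total: float = 1.0
    tau: float = 1.0
    a0: float = 1.0
    b0: float = 1.0
    max_parents: int = 3

    def __post_init__(self) -> None:
        for name in ("dirichlet_alpha_total", "tau", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")


class BayesNetwork:
    """A DAG with mixed node types and (after fitting) family parameters."""

    def __init__(self, nodes: list[NodeSpec],
                 edges: list[tuple[str, str]] | None = None):
        names = [n.name for n in nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        self.specs: dict[str, NodeSpec] = {n.name: n for n in nodes}
        self.order: list[str] = names
        self.parents: dict[str, list[str]] = {n: [] for n in names}
        self.parameters: dict[str, dict] = {}
        self._reach = np.zeros((len(names), len(names)), dtype=bool)
        self._idx = {n: i for i, n in enumerate(names)}
        for p, c in edges or []:
            self.add_edge(p, c)

    # -- structure -------------------------------------------------------

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, ps in self.parents.items() for p in ps]

    def children(self, node: str) -> list[str]:
        return [c for c, ps in self.parents.items() if node in ps]

    def creates_cycle(self, parent: str, child: str) -> bool:
        return parent == child or self._reach[self._idx[child],
                                              self._idx[parent]]

    def violates_cg(self, parent: str, child: str) -> bool:
        return (self.specs[parent].kind == "continuous"
                and self.specs[child].kind == "discrete")

    def add_edge(self, parent: str, child: str) -> None:
        if parent not in self.specs or child not in self.specs:
            raise KeyError(f"unknown node in edge ({parent}, {child})")
        if self.violates_cg(parent, child):
            raise ValueError(
                f"CG restriction: continuous {parent!r} cannot parent "
                f"discrete {child!r}")
        if self.creates_cycle(parent, child):
            raise ValueError(f"edge {parent}->{child} would create a cycle")
        if parent in self.parents[child]:
            return
        self.parents[child].append(parent)
        i, j = self._idx[parent], self._idx[child]
        anc = self._reach[:, i].copy()
        anc[i] = True
        desc = self._reach[j, :].copy()
        desc[j] = True
        self._reach |= np.outer(anc, desc)

    def copy(self) -> "BayesNetwork":
        out = BayesNetwork(list(self.specs.values()))
        out.parents = {c: list(ps) for c, ps in self.parents.items()}
        out._reach = self._reach.copy()
        out.parameters = {}
        return out

    def is_acyclic(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.order)
        g.add_edges_from(self.edges)
        return nx.is_directed_acyclic_graph(g)

    # -- serialization ---------------------------------------------------

    def to_dict(self, tally: "EdgeTally | None" = None) -> dict:
        return {
            "nodes": [
                {"name": s.name, "kind": s.kind, "states": list(s.states)}
                for s in self.specs.values()
            ],
            "edges": [
                {
                    "parent": p,
                    "child": c,
                    "bootstrap_frequency": (
                        tally.frequency(p, c) if tally is not None else None
                    ),
                }
                for p, c in self.edges
            ],
            "parameters": _jsonable(self.parameters),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_dot(self, phenotype: str | None = None) -> str:
        degree = {n: 0 for n in self.order}
        for p, c in self.edges:
            degree[p] += 1
            degree[c] += 1
        lines = ["digraph consensus {", "  rankdir=LR;"]
        for n in self.order:
            size = 0.4 + 0.12 * degree[n]
            color = "lightblue" if n == phenotype else "gray90"
            lines.append(
                f'  "{n}" [width={size:.2f},height={size:.2f},'
                f'style=filled,fillcolor={color}];')
        for p, c in self.edges:
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class EdgeTally:
    """Directed-edge frequencies across bootstrap-learned networks."""

    counts: dict[tuple[str, str], int]
    B: int

    def frequency(self, parent: str, child: str) -> float:
        return self.counts.get((parent, child), 0) / self.B

    @property
    def frequencies(self) -> dict[tuple[str, str], float]:
        return {e: c / self.B for e, c in self.counts.items()}


@dataclass
class ConsensusSweepResult:
    trace: list[dict]
    chosen_threshold: float
    chosen_network: BayesNetwork
    chosen_auc: float
    k_folds: int

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"threshold": t["threshold"], "n_edges": t["n_edges"],
              "cv_auc": t["cv_auc"]} for t in self.trace]
        )


# ---------------------------------------------------------------- scores


def _parent_configs(columns: list[np.ndarray],
                    cards: list[int]) -> np.ndarray:
    """Mixed-radix code of each row's discrete-parent configuration."""
    if not columns:
        return np.zeros(0, dtype=np.int64)
    code = np.zeros_like(columns[0], dtype=np.int64)
    for col, card in zip(columns, cards):
        code = code * card + col
    return code


def family_score_discrete(
    child: np.ndarray,
    parent_columns: list[np.ndarray],
    n_states: int,
    parent_cards: list[int],
    config: ScoreConfig,
) -> float:
    """Log Dirichlet–multinomial evidence of a discrete family.

    Product over observed parent configurations of
    Gamma(a0)/Gamma(a0+n) * prod_s Gamma(a_s+n_s)/Gamma(a_s) with a uniform
    Dirichlet (a_s = alpha_total / n_states) per configuration.
    """
    child = np.asarray(child, dtype=np.int64)
    n = child.size
    if n == 0:
        return 0.0
    alpha0 = config.dirichlet_alpha_total
    alpha_s = alpha0 / n_states
    if parent_columns:
        code = _parent_configs(parent_columns, parent_cards)
        _, inv = np.unique(code, return_inverse=True)
        n_cfg = inv.max() + 1
        counts = np.zeros((n_cfg, n_states))
        np.add.at(counts, (inv, child), 1.0)
    else:
        counts = np.bincount(child, minlength=n_states)[None, :].astype(float)
    totals = counts.sum(axis=1)
    score = (gammaln(alpha0) - gammaln(alpha0 + totals)).sum()
    score += (gammaln(alpha_s + counts) - gammaln(alpha_s)).sum()
    return float(score)


def _nig_log_marginal(y: np.ndarray, X: np.ndarray,
                      config: ScoreConfig) -> float:
    """Closed-form evidence of y ~ N(X b, s2), b|s2 ~ N(0, s2/tau I),
    s2 ~ InvGamma(a0, b0)."""
    n, p = X.shape
    tau, a0, b0 = config.tau, config.a0, config.b0
    lam_n = tau * np.eye(p) + X.T @ X
    sign, logdet_n = np.linalg.slogdet(lam_n)
    mu_n = np.linalg.solve(lam_n, X.T @ y)
    a_n = a0 + 0.5 * n
    b_n = b0 + 0.5 * float(y @ y - mu_n @ lam_n @ mu_n)
    b_n = max(b_n, 1e-300)
    return (
        -0.5 * n * np.log(2.0 * np.pi)
        + 0.5 * (p * np.log(tau) - logdet_n)
        + a0 * np.log(b0) - a_n * np.log(b_n)
        + gammaln(a_n) - gammaln(a0)
    )


def family_score_continuous(
    child: np.ndarray,
    discrete_parent_columns: list[np.ndarray],
    continuous_parent_columns: list[np.ndarray],
    parent_cards: list[int],
    config: ScoreConfig,
) -> float:
    """Log marginal likelihood of a continuous family: one Bayesian linear
    regression (with intercept) per discrete-parent configuration, summed."""
    y = np.asarray(child, dtype=float)
    n = y.size
    if n == 0:
        return 0.0
    for col in discrete_parent_columns + continuous_parent_columns:
        if len(col) != n:
            raise ValueError("parent column length mismatch")
    X = np.column_stack(
        [np.ones(n)] + [np.asarray(c, dtype=float)
                        for c in continuous_parent_columns]
    )
    if not discrete_parent_columns:
        return _nig_log_marginal(y, X, config)
    code = _parent_configs(
        [np.asarray(c, dtype=np.int64) for c in discrete_parent_columns],
        parent_cards)
    score = 0.0
    for cfg in np.unique(code):
        sel = code == cfg
        score += _nig_log_marginal(y[sel], X[sel], config)
    return float(score)


class _Scorer:
    """Caches column arrays and family scores for one dataset."""

    def __init__(self, data: pd.DataFrame, specs: dict[str, NodeSpec],
                 config: ScoreConfig):
        self.config = config
        self.specs = specs
        self.cols: dict[str, np.ndarray] = {}
        self.cards: dict[str, int] = {}
        for name, spec in specs.items():
            col = data[name].to_numpy()
            if spec.kind == "discrete":
                self.cols[name] = col.astype(np.int64)
                self.cards[name] = len(spec.states)
            else:
                self.cols[name] = col.astype(float)
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, child: str, parents: tuple[str, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        spec = self.specs[child]
        disc = [p for p in parents if self.specs[p].kind == "discrete"]
        cont = [p for p in parents if self.specs[p].kind == "continuous"]
        if spec.kind == "discrete":
            if cont:
                raise ValueError(
                    f"continuous parent of discrete node {child!r}")
            score = family_score_discrete(
                self.cols[child], [self.cols[p] for p in disc],
                len(spec.states), [self.cards[p] for p in disc], self.config)
        else:
            score = family_score_continuous(
                self.cols[child], [self.cols[p] for p in disc],
                [self.cols[p] for p in cont],
                [self.cards[p] for p in disc], self.config)
        self._cache[key] = score
        return score


def total_score(network: BayesNetwork, data: pd.DataFrame,
                config: ScoreConfig | None = None) -> float:
    """Sum of family scores (the decomposable network posterior score)."""
    scorer = _Scorer(data, network.specs, config or ScoreConfig())
    return sum(
        scorer.family(c, tuple(ps)) for c, ps in network.parents.items()
    )


# ---------------------------------------------------------------- search

_EPS = 1e-9


def greedy_learn(
    data: pd.DataFrame,
    specs: list[NodeSpec],
    config: ScoreConfig | None = None,
    extended_moves: bool = False,
) -> BayesNetwork:
    """Add-only greedy hill climb from the empty network.

    At every step the single edge addition with the largest positive score
    improvement is applied, excluding cycle creators, CG violations and
    children already at ``max_parents``; ties break lexicographically on
    (parent, child). Stops when no addition improves the score.
    ``extended_moves`` additionally tries single-edge removals and
    reversals after the additions converge (off by default: the reference
    procedure is add-only).
    """
    config = config or ScoreConfig()
    net = BayesNetwork(specs)
    scorer = _Scorer(data, net.specs, config)
    names = net.order
    base = {c: scorer.family(c, ()) for c in names}
    deltas: dict[tuple[str, str], float] = {}
    for c in names:
        for p in names:
            if p == c or net.violates_cg(p, c):
                continue
            deltas[(p, c)] = scorer.family(c, (p,)) - base[c]
    while True:
        best_key, best_delta = None, _EPS
        for (p, c), d in sorted(deltas.items()):
            if d > best_delta and not net.creates_cycle(p, c):
                best_key, best_delta = (p, c), d
        if best_key is None:
            if extended_moves:
                net = _refine_with_removals_and_reversals(
                    net, scorer, config)
            return net
        p_star, c_star = best_key
        net.add_edge(p_star, c_star)
        base[c_star] += best_delta
        new_parents = tuple(net.parents[c_star])
        for p in names:
            key = (p, c_star)
            if key not in deltas and p != p_star:
                continue
            if (p == c_star or p in new_parents
                    or len(new_parents) >= config.max_parents):
                deltas.pop(key, None)
            else:
                deltas[key] = scorer.family(
                    c_star, new_parents + (p,)) - base[c_star]


def _refine_with_removals_and_reversals(
    net: BayesNetwork, scorer: "_Scorer", config: ScoreConfig
) -> BayesNetwork:
    """Hill climb over single-edge removals and reversals until no move
    improves the score (rebuilds the network per move; only used behind
    the ``extended_moves`` flag)."""
    while True:
        current = {c: scorer.family(c, tuple(ps))
                   for c, ps in net.parents.items()}
        best_gain, best_apply = _EPS, None
        for p, c in sorted(net.edges):
            without = tuple(x for x in net.parents[c] if x != p)
            gain_rm = scorer.family(c, without) - current[c]
            if gain_rm > best_gain:
                best_gain, best_apply = gain_rm, ("rm", p, c)
            # reversal: remove p->c, add c->p
            trial = net.copy()
            trial.parents[c] = list(without)
            trial = BayesNetwork(list(net.specs.values()),
                                 [e for e in trial.edges])
            if (not trial.violates_cg(c, p)
                    and not trial.creates_cycle(c, p)
                    and len(trial.parents[p]) < config.max_parents):
                gain_rev = (gain_rm
                            + scorer.family(p, tuple(net.parents[p]) + (c,))
                            - current[p])
                if gain_rev > best_gain:
                    best_gain, best_apply = gain_rev, ("rev", p, c)
        if best_apply is None:
            return net
        kind, p, c = best_apply
        edges = [e for e in net.edges if e != (p, c)]
        if kind == "rev":
            edges.append((c, p))
        net = BayesNetwork(list(net.specs.values()), edges)


def bootstrap_learn(
    data: pd.DataFrame,
    specs: list[NodeSpec],
    config: ScoreConfig | None = None,
    B: int = 250,
    seed: int = 0,
) -> EdgeTally:
    """Greedy-learn on ``B`` bootstrap resamples of the subjects and tally
    directed-edge frequencies."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    n = data.shape[0]
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        net = greedy_learn(data.iloc[idx].reset_index(drop=True), specs,
                           config)
        for e in net.edges:
            counts[e] = counts.get(e, 0) + 1
    return EdgeTally(counts=counts, B=B)


def consensus_network(
    tally: EdgeTally,
    specs: list[NodeSpec],
    threshold: float,
    config: ScoreConfig | None = None,
) -> BayesNetwork:
    """Insert edges with bootstrap frequency >= threshold in decreasing
    frequency order (ties lexicographic), skipping cycle creators, CG
    violations and max_parents overflows."""
    config = config or ScoreConfig()
    net = BayesNetwork(specs)
    order = sorted(tally.frequencies.items(),
                   key=lambda kv: (-kv[1], kv[0]))
    for (p, c), f in order:
        if f < threshold:
            break
        if (net.violates_cg(p, c) or net.creates_cycle(p, c)
                or len(net.parents[c]) >= config.max_parents):
            continue
        net.add_edge(p, c)
    return net


def consensus_sweep(
    tally: EdgeTally,
    data: pd.DataFrame,
    specs: list[NodeSpec],
    config: ScoreConfig | None = None,
    k_folds: int = 5,
    seed: int = 0,
    phenotype: str = "asthma_control",
) -> ConsensusSweepResult:
    """Sweep consensus thresholds over the observed bootstrap frequencies
    and pick the network maximizing stratified k-fold CV AUC for the
    phenotype (ties resolved toward the higher threshold, i.e. the sparser
    network)."""
    config = config or ScoreConfig()
    if phenotype not in data.columns:
        raise ValueError(f"phenotype {phenotype!r} absent from data")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = data[phenotype].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    class_min = int(counts[counts > 0].min())
    k = int(min(k_folds, class_min))
    if k < 2:
        raise ValueError("need at least 2 subjects in each phenotype class")
    thresholds = sorted(set(tally.frequencies.values()), reverse=True)
    trace = []
    best = None
    for thr in thresholds:
        net = consensus_network(tally, specs, thr, config)
        cv_auc = _cv_auc(net, data, phenotype, k, seed, config)
        trace.append({"threshold": thr, "n_edges": len(net.edges),
                      "network": net, "cv_auc": cv_auc})
        if best is None or cv_auc > best["cv_auc"] + 1e-12:
            best = trace[-1]
    chosen = best["network"].copy()
    fit_parameters(chosen, data, config)
    return ConsensusSweepResult(
        trace=trace,
        chosen_threshold=float(best["threshold"]),
        chosen_network=chosen,
        chosen_auc=float(best["cv_auc"]),
        k_folds=k,
    )


def _cv_auc(net: BayesNetwork, data: pd.DataFrame, phenotype: str,
            k: int, seed: int, config: ScoreConfig) -> float:
    y = data[phenotype].to_numpy(dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    scores = np.empty(len(y))
    for train, test in skf.split(np.zeros(len(y)), y):
        fold_net = net.copy()
        fit_parameters(fold_net, data.iloc[train], config)
        for i in test:
            post = predict_phenotype(fold_net, data.iloc[i], phenotype)
            scores[i] = post[1]
    return auc(scores, y)


# ---------------------------------------------------------------- fitting


def markov_neighborhood(network: BayesNetwork, node: str,
                        include_parents: bool = False) -> list[str]:
    """Children plus the children's other parents (optionally the node's
    own parents for the full Markov blanket), deduplicated and sorted."""
    if node not in network.specs:
        raise KeyError(f"unknown node {node!r}")
    out: set[str] = set()
    for c in network.children(node):
        out.add(c)
        out |= set(network.parents[c])
    if include_parents:
        out |= set(network.parents[node])
    out.discard(node)
    return sorted(out)


def fit_parameters(network: BayesNetwork, data: pd.DataFrame,
                   config: ScoreConfig | None = None) -> None:
    """Posterior-mean parameters for every family.

    Discrete: CPT entries (n_s + a_s) / (n + a0) per observed parent
    configuration, uniform prior elsewhere. Continuous: ridge-regularized
    regression coefficients (precision tau) and posterior-mean residual
    variance per discrete-parent configuration.
    """
    config = config or ScoreConfig()
    params: dict[str, dict] = {}
    for child, parents in network.parents.items():
        spec = network.specs[child]
        disc = [p for p in parents if network.specs[p].kind == "discrete"]
        cont = [p for p in parents if network.specs[p].kind == "continuous"]
        col = data[child].to_numpy()
        if spec.kind == "discrete":
            r = len(spec.states)
            alpha0 = config.dirichlet_alpha_total
            alpha_s = alpha0 / r
            fam: dict = {"kind": "discrete", "parents": disc, "cpt": {}}
            codes = [data[p].to_numpy(dtype=np.int64) for p in disc]
            if disc:
                keys = list(zip(*codes))
            else:
                keys = [()] * len(col)
            groups: dict[tuple, np.ndarray] = {}
            for key, v in zip(keys, col.astype(int)):
                groups.setdefault(tuple(int(x) for x in key), []).append(v)
            for key, vals in groups.items():
                counts = np.bincount(vals, minlength=r).astype(float)
                fam["cpt"][key] = (counts + alpha_s) / (counts.sum() + alpha0)
            fam["prior"] = np.full(r, 1.0 / r)
            marg = np.bincount(col.astype(int), minlength=r).astype(float)
            fam["marginal"] = (marg + alpha_s) / (marg.sum() + alpha0)
            fam["mode"] = int(np.argmax(marg))
            params[child] = fam
        else:
            fam = {"kind": "continuous", "disc_parents": disc,
                   "cont_parents": cont, "by_config": {},
                   "marginal_mean": float(np.nanmean(col))}
            codes = [data[p].to_numpy(dtype=np.int64) for p in disc]
            code_rows = list(zip(*codes)) if disc else [()] * len(col)
            groups = {}
            for i, key in enumerate(code_rows):
                groups.setdefault(tuple(int(x) for x in key), []).append(i)
            p_dim = 1 + len(cont)
            for key, idx in groups.items():
                idx = np.asarray(idx)
                y = col[idx].astype(float)
                X = np.column_stack(
                    [np.ones(len(idx))]
                    + [data[p].to_numpy(dtype=float)[idx] for p in cont])
                lam = config.tau * np.eye(p_dim) + X.T @ X
                mu = np.linalg.solve(lam, X.T @ y)
                a_n = config.a0 + 0.5 * len(idx)
                b_n = config.b0 + 0.5 * float(y @ y - mu @ lam @ mu)
                var = b_n / (a_n - 1.0) if a_n > 1.0 else b_n / a_n
                fam["by_config"][key] = {"coef": mu, "var": max(var, 1e-12)}
            fam["fallback"] = {
                "coef": np.zeros(p_dim),
                "var": config.b0 / config.a0,
            }
            params[child] = fam
    network.parameters = params


def _log_density_continuous(fam: dict, value: float,
                            evidence: pd.Series) -> float:
    key = tuple(int(evidence[p]) for p in fam["disc_parents"])
    entry = fam["by_config"].get(key, fam["fallback"])
    coef = np.asarray(entry["coef"], dtype=float)
    xs = np.concatenate(
        [[1.0], [float(evidence[p]) for p in fam["cont_parents"]]])
    mean = float(coef @ xs)
    var = float(entry["var"])
    return -0.5 * (np.log(2.0 * np.pi * var) + (value - mean) ** 2 / var)


def _log_prob_discrete(fam: dict, value: int, evidence: pd.Series) -> float:
    key = tuple(int(evidence[p]) for p in fam["parents"])
    probs = fam["cpt"].get(key, fam["prior"])
    return float(np.log(np.asarray(probs)[int(value)]))


def predict_phenotype(
    network: BayesNetwork,
    evidence: pd.Series,
    node: str = "asthma_control",
) -> np.ndarray:
    """Posterior over the phenotype's states given a row of evidence.

    P(state | evidence) is proportional to P(state | its parents) times the
    product over the node's children of the child's density with the node
    set to that state — only the Markov neighborhood is consulted. Missing
    evidence values are replaced by the fitted marginal mean (continuous)
    or mode (discrete), with a warning.
    """
    if node not in network.specs:
        raise KeyError(f"unknown node {node!r}")
    if not network.parameters:
        raise RuntimeError("network parameters not fitted")
    spec = network.specs[node]
    needed = set(markov_neighborhood(network, node, include_parents=True))
    ev = evidence.copy()
    for name in needed:
        if name not in ev.index or pd.isna(ev[name]):
            fam = network.parameters[name]
            fill = (fam["mode"] if fam["kind"] == "discrete"
                    else fam["marginal_mean"])
            warnings.warn(
                f"evidence missing for {name!r}; using fitted "
                f"{'mode' if fam['kind'] == 'discrete' else 'mean'}")
            ev[name] = fill
    n_states = len(spec.states)
    logp = np.zeros(n_states)
    children = network.children(node)
    fam_node = network.parameters[node]
    for s in range(n_states):
        ev_s = ev.copy()
        ev_s[node] = s
        logp[s] = _log_prob_discrete(fam_node, s, ev_s)
        for c in children:
            fam_c = network.parameters[c]
            if fam_c["kind"] == "discrete":
                logp[s] += _log_prob_discrete(fam_c, int(ev_s[c]), ev_s)
            else:
                logp[s] += _log_density_continuous(fam_c, float(ev_s[c]),
                                                   ev_s)
    if not np.isfinite(logp).any():
        warnings.warn("zero total density; returning uniform posterior")
        return np.full(n_states, 1.0 / n_states)
    logp -= logp.max()
    post = np.exp(logp)
    return post / post.sum()


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative, with
    ties credited 1/2 (the rank / Mann–Whitney formulation)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
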