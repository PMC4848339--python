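"""Synthetic procedure tables with the statistical structure the analysis
assumes, and planted partial orders for recovery testing.

Two generators:

* :func:`generate_correlated_table` draws tables from a Gaussian copula
  with block-diagonal correlation — emulating the empirically observed
  variable groupings (the two greenness scores with sample mass; solvent
  volume with its hazard-weighted counterpart; analysis time with solid
  waste and the number of co-determined analytes) — and maps latent
  normals through realistic marginals (lognormal amounts, an integer 0-4
  greenness count, bounded 0-100 scores).

* :func:`plant_poset_table` embeds a known partial order into coordinates
  (a realizer of linear extensions), optionally blurred with Gaussian
  noise, so order-reconstruction can be tested against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DEFAULT_SCHEMA, ProcedureTable, VariableSpec, schema_by_name
from .exceptions import ConfigError, EmbeddingError, ValidationError
from .poset import HasseDiagram

#: Default correlation blocks, mirroring the observed variable groupings.
#: Targets are Spearman rank correlations (monotone marginal transforms
#: preserve rank correlation, not Pearson).  A leading ``-`` marks a
#: variable negatively correlated with the rest of its block: greenness
#: scores are high exactly when the sample demand is low.
DEFAULT_BLOCKS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("nemi", "eco_scale", "-sample_mass"), 0.8),
    (("solvent_volume", "hazard_weighted_solvent"), 0.9),
    (("time_h", "solid_waste", "other_analytes"), 0.7),
)

#: Default marginals, loosely calibrated to the survey's units (sample
#: masses of grams, solvent volumes of tens of mL, analysis times of
#: hours); illustrative, not fitted to any published matrix.
DEFAULT_MARGINALS: dict[str, tuple[str, dict]] = {
    "lod": ("lognormal", {"mean_log": math.log(0.5), "sd_log": 1.0}),
    "precision": ("lognormal", {"mean_log": math.log(5.0), "sd_log": 0.5}),
    "recovery": ("truncnorm", {"loc": 95.0, "scale": 8.0, "lo": 60.0, "hi": 110.0}),
    "sample_mass": ("lognormal", {"mean_log": math.log(5.0), "sd_log": 0.8}),
    "other_analytes": ("poisson", {"mu": 8.0}),
    "solvent_volume": ("lognormal", {"mean_log": math.log(20.0), "sd_log": 0.9}),
    "hazard_weighted_solvent": ("lognormal", {"mean_log": math.log(30.0), "sd_log": 0.9}),
    "solid_waste": ("lognormal", {"mean_log": math.log(20.0), "sd_log": 1.0}),
    "time_h": ("lognormal", {"mean_log": math.log(3.0), "sd_log": 0.7}),
    "nemi": ("binomial", {"n": 4, "p": 0.55}),
    "eco_scale": ("beta_scaled", {"a": 6.0, "b": 2.5, "lo": 0.0, "hi": 100.0}),
}


@dataclass
class GeneratorConfig:
    """Configuration for the copula table generator.

    ``correlation_blocks`` are (variable names, target Spearman rho) with
    disjoint blocks; variables outside every block are independent.  A
    name prefixed with ``-`` correlates negatively with the unprefixed
    members of its block (and positively with other ``-`` members).
    """

    n_procedures: int = 41
    correlation_blocks: Sequence[tuple[Sequence[str], float]] = DEFAULT_BLOCKS
    marginals: Mapping[str, tuple[str, dict]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_procedures < 2:
            raise ConfigError("n_procedures must be >= 2")
        seen: set[str] = set()
        for names, rho in self.correlation_blocks:
            if not -1 < rho < 1:
                raise ConfigError(f"block correlation {rho} outside (-1, 1)")
            for name in names:
                name = name.lstrip("-")
                if name in seen:
                    raise ConfigError(f"variable {name!r} in two blocks")
                seen.add(name)
                if name not in self.marginals:
                    raise ConfigError(f"no marginal for block variable {name!r}")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        payload = json.loads(open(path).read())
        blocks = tuple(
            (tuple(b["variables"]), b["rho"])
            for b in payload.get("correlation_blocks", [])
        ) or DEFAULT_BLOCKS
        marginals = dict(DEFAULT_MARGINALS)
        for name, spec in payload.get("marginals", {}).items():
            marginals[name] = (spec["family"], spec["params"])
        return cls(
            n_procedures=payload.get("n_procedures", 41),
            correlation_blocks=blocks,
            marginals=marginals,
            seed=payload.get("seed", 0),
        )


def _latent_correlation(config: GeneratorConfig, names: list[str]) -> np.ndarray:
    """Block-diagonal latent normal correlation matrix.

    Latent rho is chosen so the copula's Spearman correlation matches the
    target: rho_latent = 2 sin(pi * rho_S / 6).
    """
    r = len(names)
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(r)
    for block, rho_s in config.correlation_blocks:
        rho = 2.0 * math.sin(math.pi * rho_s / 6.0)
        signed = [(n.lstrip("-"), -1.0 if n.startswith("-") else 1.0)
                  for n in block]
        for a, sa in signed:
            for b, sb in signed:
                if a != b:
                    corr[idx[a], idx[b]] = sa * sb * rho
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ConfigError("implied correlation matrix is not positive definite")
    return corr


def _apply_marginal(u: np.ndarray, family: str, params: dict) -> np.ndarray:
    if family == "lognormal":
        return stats.lognorm.ppf(u, s=params["sd_log"],
                                 scale=math.exp(params["mean_log"]))
    if family == "binomial":
        return stats.binom.ppf(u, params["n"], params["p"])
    if family == "poisson":
        return stats.poisson.ppf(u, params["mu"])
    if family == "beta_scaled":
        lo, hi = params["lo"], params["hi"]
        return lo + (hi - lo) * stats.beta.ppf(u, params["a"], params["b"])
    if family == "truncnorm":
        loc, scale = params["loc"], params["scale"]
        a = (params["lo"] - loc) / scale
        b = (params["hi"] - loc) / scale
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)
    if family == "uniform":
        return params["lo"] + (params["hi"] - params["lo"]) * u
    raise ConfigError(f"unknown marginal family {family!r}")


def generate_correlated_table(config: GeneratorConfig) -> ProcedureTable:
    """Draw a seed-deterministic procedure table from the Gaussian copula.

    Latent correlated normals (block-diagonal correlation per config) are
    mapped to each variable's marginal by the probability-integral
    transform.  Variables present in ``config.marginals`` but in no block
    are generated independently.
    """
    names = [s.name for s in DEFAULT_SCHEMA if s.name in config.marginals]
    extra = [n for n in config.marginals if n not in names]
    names += extra
    corr = _latent_correlation(config, names)
    rng = np.random.default_rng(config.seed)
    z = rng.multivariate_normal(
        np.zeros(len(names)), corr, size=config.n_procedures,
        method="cholesky",
    )
    u = stats.norm.cdf(z)
    # clip away exact 0/1 to keep ppf finite
    u = np.clip(u, 1e-12, 1 - 1e-12)
    data = {}
    for j, name in enumerate(names):
        family, params = config.marginals[name]
        data[name] = _apply_marginal(u[:, j], family, params)
    by_name = schema_by_name(DEFAULT_SCHEMA)
    variables = tuple(
        by_name.get(n, VariableSpec(n)) for n in names
    )
    values = pd.DataFrame(
        data, index=pd.RangeIndex(1, config.n_procedures + 1,
                                  name="procedure_id"),
    )
    return ProcedureTable(values[list(names)], variables)


# ---------------------------------------------------------------- planting

def _topo_with_priority(
    objects: list, pred: dict, priority: dict, force_before: tuple | None = None
) -> list:
    """Topological order choosing the highest-priority available element;
    with force_before=(u, v), u is postponed until v has been placed."""
    u = v = None
    if force_before is not None:
        u, v = force_before
    placed: set = set()
    out: list = []
    remaining = set(objects)
    while remaining:
        avail = [
            o for o in remaining
            if pred[o] <= placed and not (o == u and v not in placed)
        ]
        if not avail:
            # only u is available and v not yet placed -> must place u
            avail = [o for o in remaining if pred[o] <= placed]
        best = max(avail, key=lambda o: priority[o])
        out.append(best)
        placed.add(best)
        remaining.discard(best)
    return out


def _greedy_realizer(diagram: HasseDiagram, rng: np.random.Generator) -> list[list]:
    """Linear extensions whose pairwise-agreement intersection equals the
    planted strict order.  Greedy: start from a base extension, then add
    extensions built with reversed priorities targeting a still-agreed
    incomparable pair, until no spurious agreement remains."""
    objects = list(diagram.objects)
    pred = {o: set() for o in objects}
    for s, t in diagram.order:
        pred[t].add(s)
    base_priority = {o: -i for i, o in enumerate(objects)}
    exts = [_topo_with_priority(objects, pred, base_priority)]

    def spurious_pairs() -> list[tuple]:
        pos = [{o: i for i, o in enumerate(ext)} for ext in exts]
        out = []
        for i, a in enumerate(objects):
            for b in objects[i + 1:]:
                if diagram.comparable(a, b):
                    continue
                if all(p[a] < p[b] for p in pos):
                    out.append((a, b))
                elif all(p[b] < p[a] for p in pos):
                    out.append((b, a))
        return out

    while True:
        bad = spurious_pairs()
        if not bad:
            return exts
        u, v = bad[0]
        # reversed priority relative to the last extension breaks many
        # agreed pairs at once; force v before u to break this one surely
        rev_priority = {o: i for i, o in enumerate(exts[-1])}
        exts.append(
            _topo_with_priority(objects, pred, rev_priority, force_before=(u, v))
        )


def plant_poset_table(
    poset: HasseDiagram,
    n_variables: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ProcedureTable:
    """Coordinates realising a known partial order, plus Gaussian noise.

    Each variable is one linear extension of the poset; an object's value
    on it is its position (1..N).  The extensions form a realizer, so at
    ``noise_sd = 0`` rebuilding the dominance order from the table
    recovers the planted order exactly.

    Raises
    ------
    EmbeddingError
        If the greedy realizer needs more than ``n_variables`` orders
        (the poset's order dimension exceeds the coordinate budget).
    """
    if n_variables < 2:
        raise ValidationError("n_variables must be >= 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    exts = _greedy_realizer(poset, rng)
    if len(exts) > n_variables:
        raise EmbeddingError(
            f"poset needs {len(exts)} coordinate orders (its order dimension "
            f"is at least 2 and possibly up to {len(exts)}); "
            f"n_variables={n_variables} is too small to embed it"
        )
    objects = list(poset.objects)
    pred = {o: set() for o in objects}
    for s, t in poset.order:
        pred[t].add(s)
    while len(exts) < n_variables:
        # pad with random extensions; intersection only shrinks toward the
        # planted order and never below it
        priority = {o: rng.random() for o in objects}
        exts.append(_topo_with_priority(objects, pred, priority))

    n = len(objects)
    values = np.empty((n, n_variables), dtype=float)
    for j, ext in enumerate(exts):
        for pos, o in enumerate(ext):
            values[objects.index(o), j] = pos + 1.0
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    variables = tuple(
        VariableSpec(f"v{j + 1}", role="environmental",
                     orientation="low_is_good")
        for j in range(n_variables)
    )
    df = pd.DataFrame(
        values, index=pd.Index(objects, name="procedure_id"),
        columns=[s.name for s in variables],
    )
    return ProcedureTable(df, variables)


def random_poset(
    n: int, edge_prob: float = 0.3, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> HasseDiagram:
    """Random poset: transitive closure of a random DAG on 1..n (a shuffled
    labelling of a random upper-triangular adjacency)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    order_perm = rng.permutation(n)
    adj = rng.random((n, n)) < edge_prob
    reach = np.zeros((n, n), dtype=bool)
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if adj[i, j]:
                reach[i, j] = True
                reach[i] |= reach[j]
    ids = [int(order_perm[i]) + 1 for i in range(n)]
    strict = frozenset(
        (ids[i], ids[j]) for i in range(n) for j in range(n) if reach[i, j]
    )
    from .poset import transitive_reduction

    return transitive_reduction(HasseDiagram(tuple(sorted(ids)), strict))
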