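"""Assessment pipeline: PCA overview, environmental/metrological partial-
order rankings, level-wise score summaries, and the bivariate greenness /
performance table.

The core is :class:`HasseRanking`, a scikit-learn style estimator: ``fit``
takes a procedure table, enforces completeness, orients the variables,
builds the dominance order and its Hasse diagram, and computes structural
descriptors and averaged ranks.  Module-level functions
(:func:`rank_procedures`, :func:`level_summary`,
:func:`bivariate_rank_table`, :func:`pca_overview`) are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import (
    DEFAULT_SCHEMA,
    ENVIRONMENTAL_VARIABLES,
    METROLOGICAL_VARIABLES,
    ProcedureTable,
    VariableSpec,
    validate_completeness,
)
from .exceptions import GreenrankError, ValidationError
from .extensions import EXACT_THRESHOLD_DEFAULT, RankVector, average_ranks
from .poset import (
    HasseDiagram,
    OrientedMatrix,
    PosetSummary,
    build_order,
    orient_matrix,
    summarize,
    transitive_reduction,
)


class PipelineStageError(GreenrankError):
    """Error raised by a pipeline stage, labelled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass
class RankingResult:
    """Full provenance of one partial-order ranking run."""

    diagram: HasseDiagram
    summary: PosetSummary
    ranks: RankVector
    variable_set: tuple[str, ...]
    orientation_audit: dict[str, str]
    dropped_ids: tuple = ()

    @property
    def average_ranks(self) -> pd.Series:
        """Averaged rank for every procedure id (class members included)."""
        expanded = self.ranks.expanded(self.diagram)
        return pd.Series(expanded, name="average_rank").sort_index()

    @property
    def levels(self) -> pd.Series:
        """Level for every procedure id (class members included)."""
        out = {}
        for rep, level in self.summary.levels.items():
            for member in self.diagram.equivalence_classes[rep]:
                out[member] = level
        return pd.Series(out, name="level").sort_index()


class HasseRanking(BaseEstimator):
    """Partial-order ranking of procedures by coordinate-wise dominance.

    Fitting builds the dominance order over the selected variables (one
    procedure precedes another only if it is at least as good on every
    variable), its Hasse diagram, the level layering (level 1 = best end),
    and averaged ranks over linear extensions — exact for small posets,
    Bubley-Dyer sampled otherwise.

    Parameters
    ----------
    variables : sequence of str, optional
        Explicit information basis.  If None, chosen from ``role``.
    role : {"environmental", "metrological"}, optional
        Select the default variable set for the role (ignored when
        ``variables`` is given).  Default "environmental".
    include_scores : bool
        Add the NEMI and Eco-Scale columns to the environmental basis.
    exact_threshold : int
        Largest poset ranked exactly; larger ones are sampled.
    n_samples, burn_in, thinning : int
        Bubley-Dyer sampler settings (burn_in/thinning default to N^3 / N).
    random_state : int, optional
        Seed for the sampler; required if sampling is triggered.

    Attributes
    ----------
    diagram_ : HasseDiagram
    summary_ : PosetSummary
    ranks_ : RankVector
    average_ranks_ : pandas.Series  (per procedure id)
    levels_ : pandas.Series  (per procedure id)
    maximal_, minimal_, isolated_ : frozenset
    height_, width_ : int
    orientation_audit_ : dict
    result_ : RankingResult
    """

    def __init__(
        self,
        variables: Sequence[str] | None = None,
        role: str = "environmental",
        include_scores: bool = False,
        exact_threshold: int = EXACT_THRESHOLD_DEFAULT,
        n_samples: int = 10_000,
        burn_in: int | None = None,
        thinning: int | None = None,
        random_state: int | None = None,
    ):
        self.variables = variables
        self.role = role
        self.include_scores = include_scores
        self.exact_threshold = exact_threshold
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.thinning = thinning
        self.random_state = random_state

    def _variable_set(self) -> tuple[str, ...]:
        if self.variables is not None:
            return tuple(self.variables)
        if self.role == "environmental":
            base = ENVIRONMENTAL_VARIABLES
            if self.include_scores:
                base = base + ("nemi", "eco_scale")
            return base
        if self.role == "metrological":
            return METROLOGICAL_VARIABLES
        raise ValidationError(f"unknown role {self.role!r}")

    def fit(self, X: ProcedureTable | pd.DataFrame, y=None):
        """Fit the ranking on a ProcedureTable (or a DataFrame interpreted
        with the default schema)."""
        table = _as_table(X)
        variable_set = self._variable_set()

        def stage(name, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GreenrankError as err:
                raise PipelineStageError(name, err) from err

        complete = stage(
            "validate_completeness", validate_completeness, table, variable_set
        )
        matrix = stage("orient_matrix", orient_matrix, complete, variable_set)
        diagram = stage(
            "transitive_reduction", transitive_reduction,
            stage("build_order", build_order, matrix),
        )
        summary = stage("summarize", summarize, diagram)
        ranks = stage(
            "average_ranks", average_ranks, diagram,
            exact_threshold=self.exact_threshold,
            n_samples=self.n_samples, burn_in=self.burn_in,
            thinning=self.thinning, seed=self.random_state,
        )
        self.variable_set_ = tuple(matrix.variable_names)
        self.diagram_ = diagram
        self.summary_ = summary
        self.ranks_ = ranks
        self.orientation_audit_ = dict(matrix.orientation_audit)
        self.maximal_ = summary.maximal
        self.minimal_ = summary.minimal
        self.isolated_ = summary.isolated
        self.height_ = summary.height
        self.width_ = summary.width
        self.result_ = RankingResult(
            diagram, summary, ranks, self.variable_set_,
            self.orientation_audit_, complete.dropped_ids,
        )
        self.average_ranks_ = self.result_.average_ranks
        self.levels_ = self.result_.levels
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        """Fit and return the averaged rank per procedure id."""
        return self.fit(X).average_ranks_


def _as_table(X) -> ProcedureTable:
    if isinstance(X, ProcedureTable):
        return X
    if isinstance(X, pd.DataFrame):
        from .data import schema_by_name

        by_name = schema_by_name(DEFAULT_SCHEMA)
        variables = tuple(
            by_name.get(c, VariableSpec(c)) for c in X.columns
        )
        return ProcedureTable(X.astype(float), variables)
    raise ValidationError(
        f"expected ProcedureTable or DataFrame, got {type(X).__name__}"
    )


def rank_procedures(
    table: ProcedureTable,
    role: str = "environmental",
    variables: Sequence[str] | None = None,
    include_scores: bool = False,
    exact_threshold: int = EXACT_THRESHOLD_DEFAULT,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> RankingResult:
    """One-call ranking pipeline; see :class:`HasseRanking`."""
    est = HasseRanking(
        variables=variables, role=role, include_scores=include_scores,
        exact_threshold=exact_threshold, n_samples=n_samples,
        random_state=seed,
    )
    return est.fit(table).result_


@dataclass
class LevelSummary:
    """Mean external score (e.g. Eco-Scale) per diagram level.

    Isolated procedures are excluded from level means and summarised as
    their own group; procedures without a score are listed, not imputed.
    """

    per_level_mean_score: dict[int, float]
    isolated_mean_score: float | None
    members: dict[int, tuple]
    isolated_members: tuple
    missing_score_ids: tuple


def level_summary(
    ranking: RankingResult, scores: Mapping | pd.Series
) -> LevelSummary:
    """Average an external per-procedure score over diagram levels."""
    scores = pd.Series(dict(scores), dtype=float)
    levels = ranking.levels
    isolated_members = tuple(
        m for rep in ranking.summary.isolated
        for m in ranking.diagram.equivalence_classes[rep]
    )
    missing = tuple(
        pid for pid in levels.index
        if pid not in scores.index or pd.isna(scores.get(pid))
    )
    members: dict[int, list] = {}
    sums: dict[int, list] = {}
    for pid, level in levels.items():
        if pid in isolated_members:
            continue
        members.setdefault(level, []).append(pid)
        if pid not in missing:
            sums.setdefault(level, []).append(scores[pid])
    per_level = {
        level: float(np.mean(vals)) for level, vals in sorted(sums.items())
    }
    iso_scores = [scores[m] for m in isolated_members if m not in missing]
    iso_mean = float(np.mean(iso_scores)) if iso_scores else None
    return LevelSummary(
        per_level_mean_score=per_level,
        isolated_mean_score=iso_mean,
        members={lv: tuple(v) for lv, v in sorted(members.items())},
        isolated_members=isolated_members,
        missing_score_ids=missing,
    )


def bivariate_rank_table(
    env: RankingResult, met: RankingResult
) -> pd.DataFrame:
    """Join environmental and metrological averaged ranks per procedure.

    Returns one row per procedure present in both rankings, with columns
    ``greenness_rank`` (environmental) and ``performance_rank``
    (metrological), plus ``pareto`` flagging rows not dominated on both
    axes (lower rank = better on both).  "Lower-left corner" procedures of
    a bivariate rank plot are exactly the Pareto-flagged ones and their
    near neighbours.
    """
    g = env.average_ranks.rename("greenness_rank")
    p = met.average_ranks.rename("performance_rank")
    joined = pd.concat([g, p], axis=1, join="inner")
    if joined.empty:
        raise ValidationError("rankings share no procedure")
    ranks = joined.to_numpy()
    n = len(joined)
    pareto = np.ones(n, dtype=bool)
    for i in range(n):
        better = (
            (ranks <= ranks[i]).all(axis=1) & (ranks < ranks[i]).any(axis=1)
        )
        if better.any():
            pareto[i] = False
    joined["pareto"] = pareto
    joined.index.name = "procedure_id"
    return joined.sort_index()


def pca_overview(
    table: ProcedureTable, variable_set: Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal-component overview of the selected (complete) columns.

    Columns are standardised to zero mean / unit variance; the
    decomposition is by SVD.  Returns (scores, loadings,
    explained_variance_fractions); loadings are correlation loadings
    (variable-PC correlations), so the rows of ``loadings`` reproduce the
    correlation matrix as L L^T.
    """
    matrix = orient_matrix(table, variable_set)  # reuse completeness check
    names = list(matrix.variable_names)
    X = table.values[names].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 procedures")
    std = X.std(axis=0, ddof=1)
    constant = [names[j] for j in range(len(names)) if std[j] == 0]
    if constant:
        raise ValidationError(f"constant column(s): {constant}")
    Z = (X - X.mean(axis=0)) / std
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n = X.shape[0]
    eigvals = S**2 / (n - 1)
    explained = eigvals / eigvals.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=table.values.index, columns=comp_names)
    loadings = pd.DataFrame(
        Vt.T * np.sqrt(eigvals), index=names, columns=comp_names
    )
    return scores, loadings, explained
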