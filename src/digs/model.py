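"""The pathway-activity MILP.

For one pathway with standardised member-gene expression G_sm (samples s,
genes m) the model learns a signed weight per gene and one activity interval
per phenotype class such that

* pathway activity is the weighted sum  pa_s = Σ_m G_sm (rp_m − rn_m),
* at most one of rp_m, rn_m is positive for each gene (a binary selector L_m),
* absolute weights sum to one,  Σ_m (rp_m + rn_m) = 1,
* at most ``NoG`` genes carry non-zero weight (binary activity flags W_m),
* each class owns an interval [LO_c, UP_c]; intervals of different classes
  may not overlap and are separated by at least ε (order binaries Y_kc),
* a binary enclosure flag E_s marks samples whose activity falls inside
  their own class interval,

and minimises the number of samples left outside their class interval,
Σ_s (1 − E_s).  The big-U constant deactivates the enclosure and ordering
constraints when the corresponding binary is off; because absolute weights
sum to one, |pa_s| ≤ max|G|, so ``U = 2·max|G| + 2ε + 1`` is provably large
enough and is the default.

:class:`DigsModel` wraps one pathway matrix; :meth:`DigsModel.fit` solves the
MILP and returns :class:`DigsResults` with the weights, class ranges,
enclosure flags and a ``summary()`` table.  :func:`solve_digs` is the
functional shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SolverTimeoutError, ValidationError
from .preprocess import StandardizedPathwayMatrix
from .solver import HighsBackend, MilpBackend, MilpProblem

__all__ = [
    "DigsConfig",
    "DigsModel",
    "DigsResults",
    "resolve_big_u",
    "solve_digs",
    "compute_activity",
    "predict_enclosure",
    "ACTIVE_TOL",
]

#: weight magnitude above which a gene counts as active (solver tolerance)
ACTIVE_TOL = 1e-6


@dataclass
class DigsConfig:
    """Tunable parameters of the pathway MILP.

    nog
        Maximum number of genes allowed non-zero weight; ``"all"`` lifts the
        cap to the pathway size.  Default 10.
    u
        Big-U constant; ``"auto"`` derives a provably sufficient value from
        the data (see :func:`resolve_big_u`).
    epsilon
        Minimum separation between class intervals on the standardised
        activity scale.  Default 1e-3.
    mip_gap, time_limit_s
        Relative optimality gap (default 0: prove optimality) and wall-clock
        limit per solve (default 200 s; the incumbent is returned when it
        triggers).
    solver_seed
        Recorded for backends that expose a seed; the default HiGHS backend
        is deterministic and ignores it.
    """

    nog: int | str = 10
    u: float | str = "auto"
    epsilon: float = 1e-3
    mip_gap: float = 0.0
    time_limit_s: float = 200.0
    solver_seed: int = 0

    def __post_init__(self) -> None:
        if self.nog != "all" and (not isinstance(self.nog, (int, np.integer)) or self.nog < 1):
            raise ValidationError(f"nog must be a positive integer or 'all', got {self.nog!r}")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.mip_gap < 0:
            raise ValidationError("mip_gap must be ≥ 0")
        if self.time_limit_s <= 0:
            raise ValidationError("time_limit_s must be positive")
        if self.u != "auto" and self.u <= 0:
            raise ValidationError("u must be positive or 'auto'")


def resolve_big_u(matrix: StandardizedPathwayMatrix, config: DigsConfig) -> float:
    """Resolve the big-U constant for *matrix* under *config*.

    With absolute weights summing to one, every activity satisfies
    |pa_s| ≤ max|G|, so ``2·max|G| + 2ε + 1`` deactivates the enclosure and
    ordering constraints exactly when their binary is off.
    """
    if config.u != "auto":
        u = float(config.u)
    else:
        gmax = float(np.abs(matrix.values.to_numpy()).max()) if matrix.values.size else 0.0
        u = 2.0 * gmax + 2.0 * config.epsilon + 1.0
    if u <= 0:
        raise ValidationError(f"resolved big-U must be positive, got {u}")
    return u


class DigsModel:
    """MILP pathway-activity model for one standardised pathway matrix.

    Parameters
    ----------
    matrix
        The S × M standardised submatrix with complete sample labels.
    config
        Solver and formulation parameters; defaults to ``DigsConfig()``.
    backend
        MILP backend; defaults to HiGHS via scipy.
    """

    def __init__(
        self,
        matrix: StandardizedPathwayMatrix,
        config: DigsConfig | None = None,
        backend: MilpBackend | None = None,
    ):
        if matrix.n_genes < 1:
            raise ValidationError("pathway matrix has no genes")
        if matrix.n_classes < 2:
            raise ValidationError("need at least two classes")
        counts = matrix.class_sample_counts()
        empty = [c for c, n in counts.items() if n == 0]
        if empty:
            raise ValidationError(f"classes with zero samples: {empty}")
        self.matrix = matrix
        self.config = config or DigsConfig()
        self.backend = backend or HighsBackend()
        self.big_u = resolve_big_u(matrix, self.config)
        self.nog = (
            matrix.n_genes if self.config.nog == "all" else min(int(self.config.nog), matrix.n_genes)
        )

    # ---- variable layout ------------------------------------------------
    def _layout(self):
        M, S, C = self.matrix.n_genes, self.matrix.n_samples, self.matrix.n_classes
        pairs = [(k, c) for k in range(C) for c in range(C) if k < c]
        idx = {}
        off = 0
        for name, size in [
            ("rp", M), ("rn", M), ("L", M), ("W", M),
            ("E", S), ("pa", S), ("LO", C), ("UP", C), ("Y", len(pairs)),
        ]:
            idx[name] = np.arange(off, off + size)
            off += size
        return idx, off, pairs

    def build_problem(self) -> MilpProblem:
        """Assemble the MILP in matrix form (min c·x, Ax ≤ b, A_eq x = b_eq)."""
        mat = self.matrix
        G = mat.values.to_numpy(dtype=float)
        M, S, C = mat.n_genes, mat.n_samples, mat.n_classes
        idx, n_var, pairs = self._layout()
        U, eps = self.big_u, self.config.epsilon
        labels = mat.label_array()
        class_of = {c: i for i, c in enumerate(mat.class_names)}
        ci = np.asarray([class_of[l] for l in labels])

        rows_ub, b_ub = [], []
        rows_eq, b_eq = [], []

        def row():
            return np.zeros(n_var)

        # activity definition: pa_s − Σ_m G_sm (rp_m − rn_m) = 0
        for s in range(S):
            r = row()
            r[idx["pa"][s]] = 1.0
            r[idx["rp"]] -= G[s]
            r[idx["rn"]] += G[s]
            rows_eq.append(r)
            b_eq.append(0.0)
        # one-sided weights: rp_m ≤ L_m ; rn_m ≤ 1 − L_m
        for m in range(M):
            r = row(); r[idx["rp"][m]] = 1.0; r[idx["L"][m]] = -1.0
            rows_ub.append(r); b_ub.append(0.0)
            r = row(); r[idx["rn"][m]] = 1.0; r[idx["L"][m]] = 1.0
            rows_ub.append(r); b_ub.append(1.0)
        # normalisation: Σ (rp + rn) = 1
        r = row(); r[idx["rp"]] = 1.0; r[idx["rn"]] = 1.0
        rows_eq.append(r); b_eq.append(1.0)
        # gene activity flags and cardinality cap
        for m in range(M):
            r = row()
            r[idx["rp"][m]] = 1.0; r[idx["rn"][m]] = 1.0; r[idx["W"][m]] = -1.0
            rows_ub.append(r); b_ub.append(0.0)
        r = row(); r[idx["W"]] = 1.0
        rows_ub.append(r); b_ub.append(float(self.nog))
        # enclosure: E_s = 1 forces LO_{c_s} ≤ pa_s ≤ UP_{c_s}
        for s in range(S):
            c = ci[s]
            r = row()
            r[idx["LO"][c]] = 1.0; r[idx["pa"][s]] = -1.0; r[idx["E"][s]] = U
            rows_ub.append(r); b_ub.append(U)
            r = row()
            r[idx["pa"][s]] = 1.0; r[idx["UP"][c]] = -1.0; r[idx["E"][s]] = U
            rows_ub.append(r); b_ub.append(U)
        # non-overlap with ε gap, ordered by the class-pair binaries
        for p, (k, c) in enumerate(pairs):
            r = row()
            r[idx["UP"][k]] = 1.0; r[idx["LO"][c]] = -1.0; r[idx["Y"][p]] = U
            rows_ub.append(r); b_ub.append(U - eps)
            r = row()
            r[idx["UP"][c]] = 1.0; r[idx["LO"][k]] = -1.0; r[idx["Y"][p]] = -U
            rows_ub.append(r); b_ub.append(-eps)

        # objective: minimise Σ (1 − E_s)  ⇔  minimise −Σ E_s.  A tiny
        # sparsity term δ·Σ W_m with δ·M < 1 breaks ties among alternate
        # optima towards the fewest active genes without ever trading a
        # correctly enclosed sample for sparsity.
        cvec = np.zeros(n_var)
        cvec[idx["E"]] = -1.0
        cvec[idx["W"]] = 0.5 / M

        lb = np.full(n_var, -np.inf)
        ub = np.full(n_var, np.inf)
        integrality = np.zeros(n_var)
        for name in ("rp", "rn"):
            lb[idx[name]] = 0.0; ub[idx[name]] = 1.0
        for name in ("L", "W", "E", "Y"):
            lb[idx[name]] = 0.0; ub[idx[name]] = 1.0
            integrality[idx[name]] = 1
        gmax = float(np.abs(G).max()) if G.size else 0.0
        lb[idx["pa"]] = -gmax; ub[idx["pa"]] = gmax
        for name in ("LO", "UP"):
            lb[idx[name]] = -U; ub[idx[name]] = U

        return MilpProblem(
            c=cvec,
            A_ub=np.asarray(rows_ub), b_ub=np.asarray(b_ub),
            A_eq=np.asarray(rows_eq), b_eq=np.asarray(b_eq),
            lb=lb, ub=ub, integrality=integrality,
        )

    def fit(self) -> "DigsResults":
        """Solve the MILP and return the fitted results.

        Raises :class:`SolverTimeoutError` when the time limit triggers
        before any feasible incumbent exists; returns the incumbent with
        ``status="feasible_time_limit"`` when one does.
        """
        problem = self.build_problem()
        res = self.backend.solve(
            problem,
            time_limit_s=self.config.time_limit_s,
            mip_gap=self.config.mip_gap,
            seed=self.config.solver_seed,
        )
        if res.status in ("no_incumbent",):
            raise SolverTimeoutError(self.matrix.pathway_name, self.config.time_limit_s)
        if res.status == "infeasible":  # cannot happen on valid input
            raise RuntimeError(
                f"MILP reported infeasible for pathway {self.matrix.pathway_name!r}"
            )
        idx, _, pairs = self._layout()
        x = res.x
        mat = self.matrix
        genes, samples, classes = mat.member_gene_ids, mat.sample_ids, mat.class_names
        rp = pd.Series(np.clip(x[idx["rp"]], 0.0, 1.0), index=genes, name="rp")
        rn = pd.Series(np.clip(x[idx["rn"]], 0.0, 1.0), index=genes, name="rn")
        E = pd.Series(np.rint(x[idx["E"]]).astype(int), index=samples, name="E")
        return DigsResults(
            model=self,
            rp=rp,
            rn=rn,
            L=pd.Series(np.rint(x[idx["L"]]).astype(int), index=genes, name="L"),
            W=pd.Series(np.rint(x[idx["W"]]).astype(int), index=genes, name="W"),
            E=E,
            lo=pd.Series(x[idx["LO"]], index=classes, name="LO"),
            up=pd.Series(x[idx["UP"]], index=classes, name="UP"),
            Y={(classes[k], classes[c]): int(round(x[idx["Y"][p]]))
               for p, (k, c) in enumerate(pairs)},
            objective=int(len(samples) - int(E.sum())),
            status=res.status,
            mip_gap=res.mip_gap,
        )

    def write_lp(self, path: str | Path) -> None:
        """Export the model in CPLEX LP text format for cross-checking."""
        problem = self.build_problem()
        idx, n_var, pairs = self._layout()
        names = np.empty(n_var, dtype=object)
        for key, positions in idx.items():
            for j, p in enumerate(positions):
                names[p] = f"{key}_{j}"

        def expr(row: np.ndarray) -> str:
            terms = []
            for j in np.nonzero(row)[0]:
                coef = row[j]
                sign = "+" if coef >= 0 else "-"
                terms.append(f"{sign} {abs(coef):.12g} {names[j]}")
            return " ".join(terms) if terms else "0 " + names[0]

        lines = ["Minimize", " obj: " + expr(problem.c), "Subject To"]
        for i, (row, b) in enumerate(zip(problem.A_ub, problem.b_ub)):
            lines.append(f" c_ub{i}: {expr(row)} <= {b:.12g}")
        for i, (row, b) in enumerate(zip(problem.A_eq, problem.b_eq)):
            lines.append(f" c_eq{i}: {expr(row)} = {b:.12g}")
        lines.append("Bounds")
        for j in range(n_var):
            lo, hi = problem.lb[j], problem.ub[j]
            lines.append(f" {lo:.12g} <= {names[j]} <= {hi:.12g}")
        lines.append("Generals")
        lines.append(" " + " ".join(names[j] for j in np.nonzero(problem.integrality)[0]))
        lines.append("End")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class DigsResults:
    """Fitted pathway MILP: weights, class ranges, enclosures, diagnostics."""

    model: DigsModel
    rp: pd.Series
    rn: pd.Series
    L: pd.Series
    W: pd.Series
    E: pd.Series
    lo: pd.Series
    up: pd.Series
    Y: dict
    objective: int
    status: str
    mip_gap: float | None = None
    _weight: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._weight = (self.rp - self.rn).rename("weight")

    @property
    def weight(self) -> pd.Series:
        """Signed per-gene coefficients rp − rn, indexed by gene."""
        return self._weight

    @property
    def active_genes(self) -> list[str]:
        """Genes with non-negligible absolute weight (rp + rn > tolerance)."""
        mask = (self.rp + self.rn) > ACTIVE_TOL
        return list(self.rp.index[mask])

    def activity(self, values: pd.DataFrame | None = None) -> pd.Series:
        """Pathway activity pa_s for the training matrix or new samples.

        *values* must be samples × genes covering the member genes, already
        standardised with the training parameters.
        """
        if values is None:
            values = self.model.matrix.values
        return compute_activity(self.weight, values)

    def predict_enclosure(self, activity: float) -> str:
        """Class whose learned interval contains *activity*, else ``"none"``."""
        return predict_enclosure(self, activity)

    def predict(self, values: pd.DataFrame | None = None) -> pd.Series:
        """Interval-membership class per sample (diagnostic, may be "none")."""
        act = self.activity(values)
        return pd.Series([self.predict_enclosure(a) for a in act], index=act.index)

    def summary(self) -> str:
        """Human-readable fit report."""
        mat = self.model.matrix
        cfg = self.model.config
        lines = [
            "DIGS pathway-activity fit",
            "=" * 60,
            f"pathway:        {mat.pathway_name}",
            f"genes (M):      {mat.n_genes}    samples (S): {mat.n_samples}"
            f"    classes (C): {mat.n_classes}",
            f"NoG:            {self.model.nog}    epsilon: {cfg.epsilon:g}"
            f"    big-U: {self.model.big_u:g}",
            f"status:         {self.status}",
            f"misclassified:  {self.objective} / {mat.n_samples}",
            "-" * 60,
            "active genes (weight = rp - rn):",
        ]
        for g in self.active_genes:
            lines.append(f"  {g:<20s} {self.weight[g]:+.6f}")
        lines.append("-" * 60)
        lines.append("class activity ranges:")
        for c in mat.class_names:
            lo, up = self.lo[c], self.up[c]
            tag = "  (empty)" if up < lo else ""
            lines.append(f"  {c:<20s} [{lo:+.6f}, {up:+.6f}]{tag}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def constraint_report(self, tol: float = 1e-6) -> dict:
        """Residuals of every formulation invariant (all should be ≤ tol)."""
        w_abs = self.rp + self.rn
        act = self.activity()
        labels = self.model.matrix.label_array()
        eps = self.model.config.epsilon
        enclosure_viol = 0.0
        for s, sample in enumerate(self.E.index):
            if self.E.iloc[s] == 1:
                c = labels[s]
                enclosure_viol = max(
                    enclosure_viol,
                    self.lo[c] - act.iloc[s],
                    act.iloc[s] - self.up[c],
                )
        sep_viol = 0.0
        for (k, c) in self.Y:
            gap_kc = self.lo[c] - self.up[k]  # k below c
            gap_ck = self.lo[k] - self.up[c]  # c below k
            sep_viol = max(sep_viol, eps - max(gap_kc, gap_ck))
        return {
            "abs_weight_sum_err": abs(float(w_abs.sum()) - 1.0),
            "two_sided_weight_max": float(np.minimum(self.rp, self.rn).max()),
            "n_active": len(self.active_genes),
            "nog": self.model.nog,
            "enclosure_violation": float(enclosure_viol),
            "separation_violation": float(sep_viol),
            "objective_mismatch": abs(self.objective - int((self.E == 0).sum())),
        }


def solve_digs(
    matrix: StandardizedPathwayMatrix,
    config: DigsConfig | None = None,
    backend: MilpBackend | None = None,
) -> DigsResults:
    """Build and solve the pathway MILP — shortcut for ``DigsModel(...).fit()``."""
    return DigsModel(matrix, config=config, backend=backend).fit()


def compute_activity(
    weights: pd.Series | Sequence[float], values: pd.DataFrame
) -> pd.Series:
    """pa_s = Σ_m G_sm · weight_m for every sample row of *values*."""
    if isinstance(weights, pd.Series):
        missing = weights.index.difference(values.columns)
        if len(missing):
            raise ValidationError(f"samples lack member genes {list(missing[:5])}")
        aligned = values.loc[:, weights.index].to_numpy(dtype=float)
        w = weights.to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != values.shape[1]:
            raise ValidationError(
                f"weight length {w.shape[0]} ≠ gene count {values.shape[1]}"
            )
        aligned = values.to_numpy(dtype=float)
    return pd.Series(aligned @ w, index=values.index, name="activity")


def predict_enclosure(solution: DigsResults, activity: float, tol: float = 1e-6) -> str:
    """The unique class whose interval contains *activity*, or ``"none"``.

    Uniqueness is guaranteed by the ε-separated, non-overlapping ranges; a
    small *tol* absorbs solver round-off at interval borders (kept well below
    the ε separation so it cannot make two classes match).
    """
    for c in solution.lo.index:
        if solution.lo[c] - tol <= activity <= solution.up[c] + tol:
            return c
    return "none"
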