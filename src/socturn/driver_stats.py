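"""Driver attribution by blocked sequential (Type I) ANOVA.

The study design makes the drivers near-orthogonal, so sequential sums of
squares — each term's SS is the drop in residual SS when it is added after
all preceding terms — are nearly order-invariant.  Residual covariation is
screened by refitting the same model under permuted term orders: a driver
counts as significant only if p < 0.05 in EVERY tested ordering; a driver
significant in some orderings but not others is 'crossed out' (its
apparent significance is an artefact of term order, i.e. collinearity).

The biogeographical region (BGR) enters as a blocking factor.  Turnover
responses are log-transformed (natural log); DOC is analysed untransformed.

Terms are named by what they encode:
``BGR`` (region block), ``MI``/``TI`` (two-level moisture/temperature
categories), ``MI:TI`` (their interaction), ``PCo1``/``PCo2`` (soil and
landform principal coordinates), ``pH``, ``clay``, ``slope`` (numeric),
``orientation`` (slope aspect in degrees, encoded as the sin/cos pair — a
single 2-df term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "ConsistencyReport",
    "DEFAULT_EXCLUSIONS",
    "apply_exclusions",
    "sequential_anova",
    "order_consistency",
    "pearson_summary",
    "significance_code",
]

#: Site exclusions per response: trap saturation (6, 24), residual
#: diagnostics (12) for the incubation turnover; one physically
#: implausible value (40) for the radiocarbon turnover.
DEFAULT_EXCLUSIONS = {
    "log_taui": (6, 12, 24),
    "log_tau14c": (40,),
    "doc": (),
}

SIG_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_code(p: float) -> str:
    """Map a p-value to the conventional code: ***<0.001 **<0.01 *<0.05 .<0.1."""
    for thr, code in SIG_THRESHOLDS:
        if p < thr:
            return code
    return "n.s."


@dataclass(frozen=True)
class ModelSpec:
    """An ordered sequential-ANOVA model: response and term order."""

    response: str
    term_order: tuple
    exclusions: tuple | None = None  # None → DEFAULT_EXCLUSIONS[response]

    def __post_init__(self) -> None:
        object.__setattr__(self, "term_order", tuple(self.term_order))
        for i, t in enumerate(self.term_order):
            if ":" in t:
                a, b = t.split(":")
                if a not in self.term_order[:i] or b not in self.term_order[:i]:
                    # interaction immediately following its mains is fine;
                    # only reject if a main comes strictly after it
                    later = self.term_order[i + 1 :]
                    if a in later or b in later:
                        raise ValueError(
                            f"interaction {t} must not precede its main effects"
                        )


def _canonical(term: str) -> str:
    """Order-free name for a term: 'TI:MI' and 'MI:TI' are the same term."""
    if ":" in term:
        return ":".join(sorted(term.split(":")))
    return term


def apply_exclusions(
    data: pd.DataFrame,
    response: str,
    exclusions: tuple | None = None,
) -> pd.DataFrame:
    """Drop the per-response excluded sites (and saturated sites for DOC)."""
    if exclusions is None:
        exclusions = DEFAULT_EXCLUSIONS.get(response, ())
    out = data.loc[~data["site_id"].isin(list(exclusions))].copy()
    if response == "doc" and "saturated" in out.columns:
        out = out.loc[~out["saturated"].astype(bool)]
    return out


def _response_vector(data: pd.DataFrame, response: str) -> np.ndarray:
    if response == "log_tau14c":
        return np.log(data["tau_14c"].to_numpy(float))
    if response == "log_taui":
        return np.log(data["tau_i"].to_numpy(float))
    if response == "doc":
        return data["doc"].to_numpy(float)
    return data[response].to_numpy(float)


def _dummies(values: pd.Series) -> np.ndarray:
    """Treatment contrasts: indicator columns for all but the first sorted level."""
    levels = sorted(pd.unique(values.astype(str)))
    return np.column_stack(
        [(values.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(values), 0))


def term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    """Design-matrix block for one named term (n × df_term)."""
    if ":" in term:
        a, b = term.split(":")
        left, right = term_columns(data, a), term_columns(data, b)
        cols = [
            left[:, i] * right[:, j]
            for i in range(left.shape[1])
            for j in range(right.shape[1])
        ]
        return np.column_stack(cols) if cols else np.empty((len(data), 0))
    if term == "BGR":
        return _dummies(data["region"])
    if term == "MI":
        return _dummies(data["mi_cat"])
    if term == "TI":
        return _dummies(data["ti_cat"])
    if term == "orientation":
        theta = np.deg2rad(data["orientation_deg"].to_numpy(float))
        return np.column_stack([np.sin(theta), np.cos(theta)])
    col = {"PCo1": "pco1", "PCo2": "pco2", "pH": "ph"}.get(term, term)
    if col not in data.columns:
        raise KeyError(f"no column for term '{term}'")
    return data[col].to_numpy(float)[:, None]


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def sequential_anova(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Type-I ANOVA table for the given term order.

    Terms are added one at a time to an intercept-only model; each term's
    SS is the residual-SS reduction it produces, its df the rank increase
    of the design matrix.  F compares the term mean square to the full
    model's residual mean square.  Returns a DataFrame indexed by term
    (plus 'Residual') with columns df, sum_sq, mean_sq, F, p, code.
    """
    data = apply_exclusions(data, spec.response, spec.exclusions)
    y = _response_vector(data, spec.response)
    keep = np.isfinite(y)  # complete-case: drop sites lacking this response
    data, y = data.loc[keep], y[keep]
    n = len(y)
    x = np.ones((n, 1))
    rss_prev, rank_prev = _rss(x, y)
    ss_total = rss_prev  # SS about the mean
    rows = []
    for term in spec.term_order:
        block = term_columns(data, term)
        x = np.hstack([x, block])
        rss_cur, rank_cur = _rss(x, y)
        df_term = rank_cur - rank_prev
        if df_term == 0:
            raise np.linalg.LinAlgError(
                f"term '{term}' is collinear with preceding terms (adds no rank)"
            )
        rows.append((term, df_term, rss_prev - rss_cur))
        rss_prev, rank_prev = rss_cur, rank_cur
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError(f"model saturated: n={n} ≤ model df={rank_prev}")
    ms_resid = rss_prev / df_resid
    table = []
    for term, df_term, ss in rows:
        ss = max(ss, 0.0)
        ms = ss / df_term
        f = ms / ms_resid
        p = float(stats.f.sf(f, df_term, df_resid))
        table.append(
            {"term": term, "df": df_term, "sum_sq": ss, "mean_sq": ms,
             "F": f, "p": p, "code": significance_code(p)}
        )
    table.append(
        {"term": "Residual", "df": df_resid, "sum_sq": rss_prev,
         "mean_sq": ms_resid, "F": np.nan, "p": np.nan, "code": ""}
    )
    out = pd.DataFrame(table).set_index("term")
    # decomposition sanity: term SS + residual SS = total SS about the mean
    assert abs(out["sum_sq"].sum() - ss_total) <= 1e-8 * max(ss_total, 1.0)
    return out


@dataclass
class ConsistencyReport:
    """Per-term verdicts across model orderings."""

    response: str
    tables: list  # one AnovaTable per ordering
    orderings: list  # term_order tuples
    verdicts: pd.DataFrame = field(default=None)  # term × (codes..., verdict)


def order_consistency(
    data: pd.DataFrame, orderings: list[ModelSpec]
) -> ConsistencyReport:
    """Fit every ordering and screen each term for order-robust significance.

    verdict per term: 'significant' (p < 0.05 in all orderings),
    'crossed_out' (p < 0.05 in some but not all — collinearity artefact),
    'n.s.' otherwise.
    """
    if len(orderings) < 2:
        raise ValueError("need at least 2 orderings to screen consistency")
    term_sets = [frozenset(map(_canonical, s.term_order)) for s in orderings]
    if len(set(term_sets)) != 1:
        raise ValueError("orderings must share the same term set")
    if len({s.response for s in orderings}) != 1:
        raise ValueError("orderings must share the same response")
    tables = [sequential_anova(data, s) for s in orderings]
    # per ordering, map canonical term name → name used in that table
    name_maps = [{_canonical(t): t for t in s.term_order} for s in orderings]
    terms = [_canonical(t) for t in orderings[0].term_order]
    rows = {}
    for term in terms:
        ps = [float(tab.loc[m[term], "p"]) for tab, m in zip(tables, name_maps)]
        codes = [tab.loc[m[term], "code"] for tab, m in zip(tables, name_maps)]
        sig = [p < 0.05 for p in ps]
        verdict = (
            "significant" if all(sig) else "crossed_out" if any(sig) else "n.s."
        )
        row = {f"code_{i + 1}": c for i, c in enumerate(codes)}
        row.update({f"p_{i + 1}": p for i, p in enumerate(ps)})
        row["verdict"] = verdict
        rows[term] = row
    return ConsistencyReport(
        response=orderings[0].response,
        tables=tables,
        orderings=[s.term_order for s in orderings],
        verdicts=pd.DataFrame(rows).T,
    )


def pearson_summary(data: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r with two-sided t-test p for each variable pair
    (pairwise-complete observations)."""
    rows = []
    for a, b in pairs:
        sub = data[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
        xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            raise ValueError(f"zero variance in pair ({a}, {b})")
        r, p = stats.pearsonr(xa, xb)
        rows.append({"var_a": a, "var_b": b, "n": len(sub), "r": float(r),
                     "p": float(p)})
    return pd.DataFrame(rows)
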