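"""Group-comparison statistics, genotype ratios, and report assembly.

Routine statistics mirror the conventions of the quantitative analyses the
pipeline feeds: two-tailed unpaired t tests, one-way ANOVA with Tukey's
post-hoc tests, two-way ANOVA with Tukey on the cell means.  Normality is
assumed and not gatekept.  Percentages are rounded to one decimal place.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError

SIGNIFICANCE_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                       (5e-2, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in SIGNIFICANCE_LEVELS:
        if p < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class GenotypeCounts:
    wt: int
    het: int
    homo: int

    def __post_init__(self) -> None:
        if min(self.wt, self.het, self.homo) < 0:
            raise InvalidParameterError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.wt + self.het + self.homo


def genotype_ratio(counts: GenotypeCounts) -> dict:
    """Observed genotype percentages and Pearson chi-square vs 1:2:1."""
    if counts.total == 0:
        raise InvalidParameterError("zero total count")
    obs = np.array([counts.wt, counts.het, counts.homo], dtype=float)
    pct = np.round(100.0 * obs / counts.total, 1)
    expected = counts.total * np.array([0.25, 0.5, 0.25])
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return {
        "percentages": {"wt": float(pct[0]), "het": float(pct[1]),
                        "homo": float(pct[2])},
        "chi_square": float(chi2),
        "dof": 2,
        "p_value": float(p),
    }


def compare_groups(table: pd.DataFrame, design: str,
                   value_col: str = "value", group_col: str = "group",
                   region_col: str = "region") -> dict:
    """Two-group t test, one-way ANOVA + Tukey, or two-way ANOVA + Tukey.

    ``table`` is tidy: one row per replicate with group (and, for the
    two-way design, region) labels.
    """
    if design not in {"t_test", "anova1_tukey", "anova2_tukey"}:
        raise InvalidParameterError(f"unknown design {design!r}")
    groups = table[group_col].unique()
    if len(groups) < 2:
        raise InvalidParameterError("need at least two groups")
    for g in groups:
        if (table[group_col] == g).sum() < 2:
            raise InvalidParameterError(f"group {g!r} has fewer than 2 values")

    if design == "t_test":
        if len(groups) != 2:
            raise InvalidParameterError("t test needs exactly two groups")
        a = table.loc[table[group_col] == groups[0], value_col]
        b = table.loc[table[group_col] == groups[1], value_col]
        t, p = sps.ttest_ind(a, b)
        return {"design": design, "statistic": float(t), "p_value": float(p),
                "stars": significance_stars(p)}

    if design == "anova1_tukey":
        samples = [table.loc[table[group_col] == g, value_col].to_numpy()
                   for g in groups]
        f, p = sps.f_oneway(*samples)
        tukey = _tukey_table(table[value_col].to_numpy(),
                             table[group_col].astype(str).to_numpy())
        return {"design": design, "statistic": float(f), "p_value": float(p),
                "stars": significance_stars(p), "tukey": tukey}

    # two-way: group x region factorial, Tukey on the combined cells
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table.rename(columns={value_col: "value", group_col: "group",
                               region_col: "region"})
    model = ols("value ~ C(group) * C(region)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    combined = (df["group"].astype(str) + ":" + df["region"].astype(str))
    tukey = _tukey_table(df["value"].to_numpy(), combined.to_numpy())
    p_inter = float(anova.loc["C(group):C(region)", "PR(>F)"])
    return {
        "design": design,
        "anova": {str(i): {"F": float(anova.loc[i, "F"]),
                           "p": float(anova.loc[i, "PR(>F)"])}
                  for i in anova.index if np.isfinite(anova.loc[i, "F"])},
        "p_interaction": p_inter,
        "tukey": tukey,
    }


def _tukey_table(values: np.ndarray, labels: np.ndarray) -> list[dict]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values, labels)
    out = []
    for row in res.summary().data[1:]:
        g1, g2, meandiff, p_adj, lo, hi, reject = row
        out.append({"group1": str(g1), "group2": str(g2),
                    "meandiff": float(meandiff), "p_adj": float(p_adj),
                    "reject": bool(reject),
                    "stars": significance_stars(float(p_adj))})
    return out


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

def build_report(run_dir: str | Path, expected: list[str] | None = None
                 ) -> dict:
    """Assemble stage CSVs in ``run_dir`` into one deterministic summary.

    Returns {"report": ..., "text": ..., "complete": bool}; missing expected
    stages are listed and a partial report is still emitted.  Reports are
    byte-identical across runs with identical inputs (sorted keys, content
    hashes).
    """
    run_dir = Path(run_dir)
    sections: dict[str, dict] = {}
    for csv_path in sorted(run_dir.glob("*.csv")):
        df = pd.read_csv(csv_path)
        digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()[:16]
        summary: dict = {"rows": int(len(df)),
                         "columns": sorted(df.columns.tolist()),
                         "sha256_16": digest}
        numeric = df.select_dtypes("number")
        if len(numeric.columns) and len(df):
            summary["means"] = {c: round(float(numeric[c].mean()), 6)
                                for c in sorted(numeric.columns)}
        sections[csv_path.stem] = summary
    missing = sorted(set(expected or []) - set(sections))
    meta = {}
    meta_path = run_dir / "run.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    report = {"sections": sections, "missing": missing, "meta": meta}
    lines = ["# Run summary", ""]
    for name in sorted(sections):
        s = sections[name]
        lines.append(f"## {name}: {s['rows']} rows "
                     f"({', '.join(s['columns'])})")
        for c, m in s.get("means", {}).items():
            lines.append(f"  - mean {c} = {m}")
    if missing:
        lines.append("")
        lines.append("Missing stages: " + ", ".join(missing))
    return {"report": report, "text": "\n".join(lines) + "\n",
            "complete": not missing}


def write_report(run_dir: str | Path, out_dir: str | Path | None = None,
                 expected: list[str] | None = None) -> bool:
    """Write report.json + report.md into ``out_dir``; False if partial."""
    result = build_report(run_dir, expected=expected)
    out = Path(out_dir or run_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(result["report"], sort_keys=True, indent=1))
    (out / "report.md").write_text(result["text"])
    return result["complete"]
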