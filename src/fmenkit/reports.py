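"""Table-style reports for between-site comparisons.

Mirrors the published reporting conventions: per-variable mean +/- SE for
each site, a p-value rounded to 2 decimals, and significance stars.
Full-precision p-values are kept in a separate column for machine use.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .stats import stars, two_group_t, wilcoxon_rank_sum


def _site_groups(values: pd.Series, sample_sites: pd.Series):
    sites = list(dict.fromkeys(sample_sites))
    if len(sites) < 2:
        raise InputError("need at least 2 sites for a comparison report")
    a, b = sites[0], sites[1]
    va = values[sample_sites.index[sample_sites == a]].dropna()
    vb = values[sample_sites.index[sample_sites == b]].dropna()
    return a, b, va, vb


def _mean_se(v: pd.Series, decimals: int) -> str:
    return f"{v.mean():.{decimals}f} ± {sps.sem(v):.{decimals}f}"


def soil_property_report(soil: pd.DataFrame, site_column: str = "site",
                         equal_var: bool = False,
                         decimals: int = 2) -> pd.DataFrame:
    """t-test report on every numeric soil variable between the two sites."""
    sample_sites = soil[site_column]
    rows = []
    for var in soil.columns:
        if var == site_column:
            continue
        a, b, va, vb = _site_groups(soil[var], sample_sites)
        res = two_group_t(va, vb, equal_var=equal_var, label=var)
        rows.append({
            "variable": var,
            f"{a} (mean ± SE)": _mean_se(va, decimals),
            f"{b} (mean ± SE)": _mean_se(vb, decimals),
            "p": res.p_rounded,
            "p_full": res.p_value,
            "stars": res.stars,
        })
    return pd.DataFrame(rows)


def functional_comparison_report(fa: pd.DataFrame, sample_sites: pd.Series,
                                 decimals: int = 4) -> pd.DataFrame:
    """Wilcoxon rank-sum report on every functional category between sites.

    ``fa`` is a categories x samples relative-abundance matrix (%).
    """
    rows = []
    for category, values in fa.iterrows():
        a, b, va, vb = _site_groups(values, sample_sites)
        res = wilcoxon_rank_sum(va, vb, label=str(category))
        rows.append({
            "category": category,
            f"{a} (mean ± SE)": _mean_se(va, decimals),
            f"{b} (mean ± SE)": _mean_se(vb, decimals),
            "p": round(res.p_value, 4),
            "p_full": res.p_value,
            "stars": stars(res.p_value),
        })
    return pd.DataFrame(rows)
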