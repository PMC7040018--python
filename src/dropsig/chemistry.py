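"""Blood acid-base chemistry panel: derived quantities and condition structure.

The study panel holds, per participant and sampling point (rest, end of
maximal exercise, and 2/4/6-min recovery), the measured variables pH,
PCO2, PO2, [K+], [Na+], [Ca2+], [La-], [Cl-], [HCO3-], [glucose] and [Hb],
plus three derived quantities:

* strong ion difference  [SID] = ([Na+]+[K+]+[Ca2+]) - ([Cl-]+[La-])   (mmol/L)
* hydrogen ion concentration  [H+] = 10^(9 - pH)                       (nmol/L)
* blood-volume change from rest  dBV = 100*(Hb_rest/Hb_t - 1)          (%)

Exercise drops [SID] (lactate accumulation), which is the physicochemical
driver of the post-exercise acidosis; dBV < 0 reflects haemoconcentration.

``sample_panel`` draws synthetic cohorts from the published per-condition
means and SDs, with a built-in (configurable) H+/PCO2 correlation at each
condition so the resting pH-PCO2 coupling and its decay through recovery
are reproduced.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CONDITION_STATS",
    "strong_ion_difference",
    "hydrogen_ion",
    "delta_blood_volume",
    "sample_panel",
    "condition_correlation_matrices",
    "chemistry_pca_centroids",
    "PANEL_VARIABLES",
    "PCA_VARIABLES",
]

_CONDITION_ORDER = ("baseline", "peak", "rec2", "rec4", "rec6")

#: published per-condition (mean, sd) for the measured variables; glucose and
#: PO2 were not tabulated in the source study and carry invented but
#: physiologically plausible values (arterialised venous blood).
CONDITION_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "La": dict(zip(_CONDITION_ORDER, [(1.1, 0.4), (10.8, 3.1), (15.2, 2.2), (15.6, 2.2), (15.3, 2.2)])),
    "Na": dict(zip(_CONDITION_ORDER, [(141.0, 1.0), (148.0, 2.0), (146.0, 1.0), (144.0, 1.0), (143.0, 1.0)])),
    "K": dict(zip(_CONDITION_ORDER, [(4.0, 0.2), (5.4, 0.6), (4.1, 0.2), (3.8, 0.2), (3.8, 0.2)])),
    "Ca": dict(zip(_CONDITION_ORDER, [(1.23, 0.03), (1.31, 0.04), (1.28, 0.03), (1.26, 0.03), (1.24, 0.03)])),
    "Cl": dict(zip(_CONDITION_ORDER, [(105.0, 1.0), (108.0, 2.0), (107.0, 2.0), (106.0, 1.0), (106.0, 1.0)])),
    "PCO2": dict(zip(_CONDITION_ORDER, [(44.9, 4.1), (52.8, 9.9), (36.3, 3.9), (33.8, 3.2), (33.2, 2.7)])),
    "H": dict(zip(_CONDITION_ORDER, [(40.8, 2.2), (61.8, 8.6), (63.8, 7.0), (65.4, 7.2), (65.1, 7.1)])),
    "HCO3": dict(zip(_CONDITION_ORDER, [(25.7, 1.1), (18.4, 2.1), (14.8, 1.5), (14.0, 1.4), (13.9, 1.5)])),
    "Hb": dict(zip(_CONDITION_ORDER, [(15.4, 1.1), (16.7, 1.0), (16.7, 1.0), (16.6, 1.0), (16.4, 1.0)])),
    # invented defaults (not tabulated in the source study)
    "glucose": dict(zip(_CONDITION_ORDER, [(5.0, 0.5), (6.0, 0.8), (6.3, 0.7), (6.2, 0.7), (6.0, 0.7)])),
    "PO2": dict(zip(_CONDITION_ORDER, [(90.0, 8.0), (95.0, 10.0), (100.0, 9.0), (98.0, 9.0), (96.0, 9.0)])),
}

#: H+/PCO2 correlation per condition: strong at rest, decaying in recovery
DEFAULT_H_PCO2_RHO = {"baseline": 0.8, "peak": 0.45, "rec2": 0.35, "rec4": 0.30, "rec6": 0.25}

#: the 14 panel properties entering the per-condition correlation matrices
PANEL_VARIABLES = [
    "pH", "PCO2", "PO2", "K", "Na", "Ca", "La", "Cl", "HCO3", "glucose", "Hb",
    "H", "SID", "dBV",
]

#: variables kept for the chemistry PCA (pH and SID dropped: determined by the rest)
PCA_VARIABLES = ["H", "PCO2", "Hb", "dBV", "PO2", "K", "Na", "Ca", "Cl", "glucose", "La", "HCO3"]

_SID_ANALYTES = ("Na", "K", "Ca", "Cl", "La")


def strong_ion_difference(row: Mapping[str, float] | pd.DataFrame) -> float | pd.Series:
    """[SID] = ([Na+] + [K+] + [Ca2+]) - ([Cl-] + [La-]) in mmol/L."""
    if isinstance(row, pd.DataFrame):
        missing = [a for a in _SID_ANALYTES if a not in row.columns]
    else:
        missing = [a for a in _SID_ANALYTES if a not in row]
    if missing:
        raise KeyError(f"missing analytes for SID: {missing}")
    return (row["Na"] + row["K"] + row["Ca"]) - (row["Cl"] + row["La"])


def hydrogen_ion(pH):
    """[H+] in nmol/L from pH:  10^(9 - pH)."""
    pH = np.asarray(pH, dtype=float)
    out = np.power(10.0, 9.0 - pH)
    return float(out) if out.ndim == 0 else out


def delta_blood_volume(hb_rest, hb_t):
    """Percentage blood-volume change from rest, 100*(Hb_rest/Hb_t - 1).

    Negative values mean haemoconcentration (volume loss).  This is the
    haemoglobin-ratio form of the classic Hb-based estimate; the variant
    using haematocrit as well is not implemented.
    """
    hb_t = np.asarray(hb_t, dtype=float)
    if np.any(hb_t <= 0):
        raise ValueError("Hb_t must be positive")
    out = 100.0 * (np.asarray(hb_rest, dtype=float) / hb_t - 1.0)
    return float(out) if out.ndim == 0 else out


def sample_panel(
    n_participants: int = 30,
    conditions: Sequence[str] = _CONDITION_ORDER,
    seed: int = 0,
    sd_scale: float = 1.0,
    h_pco2_rho: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a synthetic chemistry panel, one row per participant per condition.

    Measured analytes are normal(mean, sd_scale*sd) truncated at 0; [H+] is
    drawn jointly with PCO2 at the per-condition correlation, and pH is
    derived from [H+].  SID and dBV are then computed from the drawn values.
    """
    rng = np.random.default_rng(seed)
    rho = dict(DEFAULT_H_PCO2_RHO)
    if h_pco2_rho:
        rho.update(h_pco2_rho)
    rows = []
    for cond in conditions:
        if cond not in CONDITION_STATS["La"]:
            raise KeyError(f"unknown condition {cond!r}")
        n = n_participants
        z_pco2 = rng.standard_normal(n)
        z_ind = rng.standard_normal(n)
        m, s = CONDITION_STATS["PCO2"][cond]
        pco2 = np.maximum(0.0, m + sd_scale * s * z_pco2)
        r = rho.get(cond, 0.0)
        m, s = CONDITION_STATS["H"][cond]
        h = np.maximum(1e-3, m + sd_scale * s * (r * z_pco2 + np.sqrt(1 - r**2) * z_ind))
        frame = {"participant": np.arange(n_participants), "condition": cond,
                 "PCO2": pco2, "H": h, "pH": 9.0 - np.log10(h)}
        for var in ("PO2", "K", "Na", "Ca", "La", "Cl", "HCO3", "glucose", "Hb"):
            m, s = CONDITION_STATS[var][cond]
            frame[var] = np.maximum(0.0, m + sd_scale * s * rng.standard_normal(n))
        rows.append(pd.DataFrame(frame))
    panel = pd.concat(rows, ignore_index=True)
    panel["SID"] = strong_ion_difference(panel)
    rest_cond = conditions[0]
    hb_rest = panel[panel["condition"] == rest_cond].set_index("participant")["Hb"]
    panel["dBV"] = delta_blood_volume(
        hb_rest.loc[panel["participant"]].to_numpy(), panel["Hb"].to_numpy()
    )
    return panel


def condition_correlation_matrices(
    panel: pd.DataFrame, variables: Sequence[str] = PANEL_VARIABLES
) -> dict[str, pd.DataFrame]:
    """Pearson correlation of the panel variables across participants, per condition.

    Zero-variance columns produce NaN rows/columns (reported as missing);
    the diagonal of defined entries is exactly 1.
    """
    out: dict[str, pd.DataFrame] = {}
    for cond, grp in panel.groupby("condition", sort=False):
        if len(grp) < 3:
            raise ValueError(f"need >= 3 participants per condition, got {len(grp)} for {cond!r}")
        out[str(cond)] = grp[list(variables)].corr()
    return out


def chemistry_pca_centroids(
    panel: pd.DataFrame,
    variables: Sequence[str] = PCA_VARIABLES,
    n_components: int = 3,
    condition_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardise the retained variables, PCA over all rows, per-condition centroids.

    Returns (scores, centroids): per-row scores PC1..PCn with labels, and the
    per-condition centroid trajectory in condition order.
    """
    missing = [v for v in variables if v not in panel.columns]
    if missing:
        raise KeyError(f"panel lacks variables: {missing}")
    X = panel[list(variables)].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = [v for v, s in zip(variables, X.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance variable(s), cannot standardise: {bad}")
    Xs = StandardScaler().fit_transform(X)
    n_components = min(n_components, Xs.shape[1], max(1, Xs.shape[0] - 1))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    score_df = pd.DataFrame(scores, columns=cols, index=panel.index)
    score_df["condition"] = panel["condition"].to_numpy()
    if condition_order is None:
        condition_order = list(dict.fromkeys(panel["condition"]))
    centroids = (
        score_df.groupby("condition", sort=False)[cols].mean().loc[list(condition_order)]
    )
    return score_df, centroids
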