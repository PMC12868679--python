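"""Per-patient feature assembly: proportions, ratios, and spatial metrics.

Feature names are structured as ``family|compartment|ref|target`` where a
phenotype token is a base cell type optionally refined by functional or
metabolic states (``macrophage+GranzymeB``, ``tumor+ATPA5.GLUT1``); the
name parses back to its components exactly.  Records are kept long
(patient, feature, family, value) until :func:`assemble_features` widens
them, imputes nulls (JSD -> 1, everything else -> 0), drops features with
fewer than 25 unique values, and standard-scales the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ARTIFACT, PanelConfig, ValidationError

SEP = "|"
STATE_SEP = "+"
COMBO_SEP = "."

VIEW_TAGS = {"cn2_label": "cn2", "cn3_label": "cn3", "mbn_label": "mbn"}

MIN_UNIQUE = 25


def feature_name(family: str, compartment: str, ref: str, target: str = "") -> str:
    for tok in (family, compartment, ref, target):
        if SEP in tok:
            raise ValidationError(f"feature token {tok!r} contains separator")
    return SEP.join([family, compartment, ref, target])


def parse_feature_name(name: str) -> tuple[str, str, str, str]:
    parts = name.split(SEP)
    if len(parts) != 4:
        raise ValidationError(f"unparseable feature name {name!r}")
    return tuple(parts)  # type: ignore[return-value]


def phenotype_token(cell_type: str, states: tuple[str, ...] = ()) -> str:
    return STATE_SEP.join([cell_type, *states]) if states else cell_type


def parse_phenotype_token(token: str) -> tuple[str, tuple[str, ...]]:
    head, *states = token.split(STATE_SEP)
    return head, tuple(states)


def _record(patient, feature, family, value):
    return {"patient_id": patient, "feature": feature, "family": family,
            "value": value}


# --------------------------------------------------------------------------
# Proportions and ratios
# --------------------------------------------------------------------------

def _phenotype_masks(
    cells: pd.DataFrame, level: str, panel: PanelConfig
) -> dict[str, np.ndarray]:
    """Boolean membership per phenotype token at the requested level."""
    types = cells["cell_type"].to_numpy()
    masks: dict[str, np.ndarray] = {}
    base_types = [t for t in panel.cell_types]
    if level == "base":
        for t in base_types:
            masks[t] = types == t
    elif level == "functional":
        states = cells["functional_states"].fillna("").to_numpy()
        for t in base_types:
            allowed = (
                panel.tumor_functional_set if t == "tumor"
                else panel.immune_functional_set
            )
            tmask = types == t
            for m in allowed:
                has = np.array([m in s.split(";") if s else False for s in states])
                masks[phenotype_token(t, (m,))] = tmask & has
    elif level == "metabolic":
        combos = cells["metabolic_states"].fillna("").to_numpy()
        seen = sorted({c for c in combos if c})
        for t in base_types:
            tmask = types == t
            for combo in seen:
                token = phenotype_token(t, (combo.replace(";", COMBO_SEP),))
                masks[token] = tmask & (combos == combo)
    else:
        raise ValidationError(f"unknown phenotype level {level!r}")
    return masks


def compartment_proportions(
    cells: pd.DataFrame, view: str, level: str, panel: PanelConfig
) -> pd.DataFrame:
    """Phenotype proportions normalized to each neighborhood compartment.

    The denominator is all non-artifact labeled cells of the compartment, so
    base-type proportions sum to 1 within it; an absent phenotype scores 0.
    Empty compartments produce no records (null, imputed downstream).
    """
    tag = VIEW_TAGS[view]
    usable = cells[(cells["cell_type"] != ARTIFACT) & cells[view].notna()]
    records = []
    for patient, psub in usable.groupby("patient_id", sort=True):
        for compartment, sub in psub.groupby(view, sort=True):
            denom = len(sub)
            if denom == 0:
                continue
            masks = _phenotype_masks(sub, level, panel)
            for token, mask in masks.items():
                records.append(_record(
                    patient,
                    feature_name(f"prop.{tag}", str(compartment), token),
                    f"prop.{tag}",
                    mask.sum() / denom,
                ))
    return pd.DataFrame(records)


def count_ratios(
    cells: pd.DataFrame, view: str, pairs=None, panel: PanelConfig | None = None
) -> pd.DataFrame:
    """Ratios of base cell-type counts within each compartment.

    A zero-count denominator yields a null (NaN) that propagates to
    imputation; when both directions are defined they are reciprocal.
    """
    tag = VIEW_TAGS[view]
    usable = cells[(cells["cell_type"] != ARTIFACT) & cells[view].notna()]
    types = sorted(usable["cell_type"].unique()) if panel is None else panel.cell_types
    if pairs is None:
        pairs = [(a, b) for a in types for b in types if a != b]
    records = []
    for patient, psub in usable.groupby("patient_id", sort=True):
        for compartment, sub in psub.groupby(view, sort=True):
            counts = sub["cell_type"].value_counts()
            for a, b in pairs:
                num, den = counts.get(a, 0), counts.get(b, 0)
                value = num / den if den > 0 else np.nan
                records.append(_record(
                    patient,
                    feature_name(f"ratio.{tag}", str(compartment), a, b),
                    f"ratio.{tag}",
                    value,
                ))
    return pd.DataFrame(records)


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Wide patient x feature matrix with raw and standardized views."""

    raw: pd.DataFrame       # imputed raw values
    scaled: pd.DataFrame    # mean 0, sd 1 per feature
    families: pd.Series     # feature -> family tag
    dropped: list[str]      # features removed by the unique-value filter

    @property
    def features(self) -> list[str]:
        return list(self.raw.columns)


def assemble_features(
    records: pd.DataFrame,
    patients,
    min_unique: int = MIN_UNIQUE,
    jsd_null: float = 1.0,
) -> FeatureMatrix:
    """Widen long records into a standardized patient x feature matrix.

    Imputation: null JSD values become ``jsd_null`` (complete separation),
    all other nulls become 0.  The unique-value filter runs before scaling
    on raw values, counting null as one value.  Assembly is deterministic
    and independent of record order.
    """
    patients = list(patients)
    if len(records) == 0:
        empty = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
        return FeatureMatrix(empty, empty.copy(), pd.Series(dtype=object), [])
    dup = records.duplicated(subset=["patient_id", "feature"])
    if dup.any():
        raise ValidationError(
            f"duplicate feature record {records.loc[dup, 'feature'].iloc[0]!r}"
        )
    families = (
        records[["feature", "family"]]
        .drop_duplicates()
        .set_index("feature")["family"]
        .sort_index()
    )
    wide = records.pivot(index="patient_id", columns="feature", values="value")
    wide = wide.reindex(index=patients, columns=families.index)
    wide.index.name = "patient_id"

    nunique = wide.nunique(dropna=False)
    keep = nunique[nunique >= min_unique].index
    dropped = [f for f in wide.columns if f not in set(keep)]
    wide = wide[keep]
    families = families.loc[keep]

    is_jsd = families.str.startswith("jsd")
    raw = wide.copy()
    raw.loc[:, is_jsd.index[is_jsd]] = raw.loc[:, is_jsd.index[is_jsd]].fillna(jsd_null)
    raw = raw.fillna(0.0)

    mu = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0).replace(0.0, 1.0)
    scaled = (raw - mu) / sd
    return FeatureMatrix(raw=raw, scaled=scaled, families=families, dropped=dropped)


# --------------------------------------------------------------------------
# Spatial metric records
# --------------------------------------------------------------------------

def _compartment_groups(cells: pd.DataFrame, view: str):
    usable = cells[(cells["cell_type"] != ARTIFACT) & cells[view].notna()]
    for patient, psub in usable.groupby("patient_id", sort=True):
        for compartment, sub in psub.groupby(view, sort=True):
            yield patient, str(compartment), sub


def gcross_records(
    cells: pd.DataFrame,
    view: str,
    panel: PanelConfig,
    level: str = "base",
    r_max: float = 150.0,
    pairs=None,
) -> pd.DataFrame:
    """Pairwise G-Cross AUC records within each compartment of ``view``.

    Both the reference and target point sets are restricted to the
    compartment.  Pairs with an empty reference or target produce no record
    (null, imputed to 0 downstream).
    """
    from .spatial import gcross_auc

    tag = VIEW_TAGS[view]
    records = []
    for patient, compartment, sub in _compartment_groups(cells, view):
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        masks = _phenotype_masks(sub, level, panel)
        tokens = [t for t, m in masks.items() if m.any()]
        if pairs is None:
            token_pairs = [(a, b) for a in tokens for b in tokens if a != b]
        else:
            token_pairs = [(a, b) for a, b in pairs if a in tokens and b in tokens]
        for a, b in token_pairs:
            res = gcross_auc(
                xy[masks[a]], xy[masks[b]], r_max=r_max,
                exclude_self=(a == b), reference_name=a, target_name=b,
            )
            if res.auc is None:
                continue
            records.append(_record(
                patient,
                feature_name(f"gcross.{tag}", compartment, a, b),
                f"gcross.{tag}",
                res.auc,
            ))
    return pd.DataFrame(records)


def jsd_records(
    cells: pd.DataFrame,
    view: str,
    panel: PanelConfig,
    level: str = "base",
    bandwidth: float | None = None,
    grid_size: int = 128,
    bw_floor: float = 10.0,
) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distance records within each compartment.

    KDE mass functions are cached per phenotype on a grid shared by all
    pairs of the compartment (core bounding box padded by three times the
    largest bandwidth), so each phenotype's intensity is estimated once.
    """
    from scipy.spatial.distance import jensenshannon

    from .spatial import _scott_bandwidth, kde_pmf

    tag = VIEW_TAGS[view]
    records = []
    for patient, compartment, sub in _compartment_groups(cells, view):
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        masks = _phenotype_masks(sub, level, panel)
        pts = {t: xy[m] for t, m in masks.items() if m.sum() >= 2}
        if len(pts) < 2:
            continue
        bws = {
            t: (bandwidth if bandwidth is not None else _scott_bandwidth(p, bw_floor))
            for t, p in pts.items()
        }
        pad = 3.0 * max(bws.values())
        gx = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, grid_size)
        gy = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, grid_size)
        pmfs = {t: kde_pmf(p, gx, gy, bws[t]) for t, p in pts.items()}
        tokens = sorted(pmfs)
        for i, a in enumerate(tokens):
            for b in tokens[i + 1:]:
                d = float(jensenshannon(pmfs[a], pmfs[b], base=2))
                records.append(_record(
                    patient,
                    feature_name(f"jsd.{tag}", compartment, a, b),
                    f"jsd.{tag}",
                    min(d, 1.0) if np.isfinite(d) else 1.0,
                ))
    return pd.DataFrame(records)


def edge_gcross_records(
    cells: pd.DataFrame,
    view: str,
    panel: PanelConfig,
    level: str = "base",
    r_max: float = 150.0,
    alpha: float | None = None,
) -> pd.DataFrame:
    """G-Cross between concave-hull edge cells of different CN regions."""
    from .spatial import edge_cells, gcross_auc

    tag = VIEW_TAGS[view]
    flags = edge_cells(cells, view=view, alpha=alpha)
    records = []
    usable = cells[(cells["cell_type"] != ARTIFACT) & cells[view].notna()]
    for patient, psub in usable.groupby("patient_id", sort=True):
        edges = {
            str(region): sub[flags.loc[sub.index]]
            for region, sub in psub.groupby(view, sort=True)
        }
        regions = sorted(edges)
        for ra in regions:
            for rb in regions:
                if ra == rb:
                    continue
                sub_a, sub_b = edges[ra], edges[rb]
                if len(sub_a) == 0 or len(sub_b) == 0:
                    continue
                masks_a = _phenotype_masks(sub_a, level, panel)
                masks_b = _phenotype_masks(sub_b, level, panel)
                for a, ma in masks_a.items():
                    if not ma.any():
                        continue
                    for b, mb in masks_b.items():
                        if not mb.any():
                            continue
                        res = gcross_auc(
                            sub_a[["x_um", "y_um"]].to_numpy(float)[ma],
                            sub_b[["x_um", "y_um"]].to_numpy(float)[mb],
                            r_max=r_max,
                        )
                        if res.auc is None:
                            continue
                        records.append(_record(
                            patient,
                            feature_name(
                                f"gcross.edge.{tag}", f"{ra}-{rb}", a, b
                            ),
                            f"gcross.edge.{tag}",
                            res.auc,
                        ))
    return pd.DataFrame(records)


def interaction_records(
    cells: pd.DataFrame,
    view: str,
    panel: PanelConfig,
    radius: float = 100.0,
    n_perm: int = 100,
    seed: int = 0,
    pairs=None,
) -> pd.DataFrame:
    """Permutation interaction z-scores per phenotype pair and compartment."""
    from .spatial import interaction_zscore

    tag = VIEW_TAGS[view]
    records = []
    for patient, compartment, sub in _compartment_groups(cells, view):
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        labels = sub["cell_type"].to_numpy()
        present = sorted(pd.unique(labels))
        if pairs is None:
            token_pairs = [(a, b) for a in present for b in present if a != b]
        else:
            token_pairs = [(a, b) for a, b in pairs if a in present and b in present]
        for a, b in token_pairs:
            z = interaction_zscore(
                xy, labels, (a, b), radius=radius, n_perm=n_perm, seed=seed
            )
            if z is None:
                continue
            records.append(_record(
                patient,
                feature_name(f"ixn.{tag}", compartment, a, b),
                f"ixn.{tag}",
                z,
            ))
    return pd.DataFrame(records)
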