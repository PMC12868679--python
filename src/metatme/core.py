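"""Shared domain model: marker panel, cell tables, clinical tables, I/O.

The pipeline's unit of data is the *cell table*: one row per segmented cell
of one TMA core, with planar centroid coordinates in micrometres, per-marker
positivity probabilities (``<marker>_prob``) and/or binary calls
(``<marker>_pos``), and the categorical annotations added by downstream
stages (``cell_type``, ``functional_states``, ``cn2_label``, ``cn3_label``,
``mbn_label``).  Cell tables are plain :class:`pandas.DataFrame` objects
with a validated column convention; the clinical table is one row per
patient with right-censored PFS/OS endpoints and the RECIST best overall
response (BOR) category.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metatme")


def configure_logging(level: int | str = logging.INFO) -> None:
    """Route package logs to stderr with a compact stage-oriented format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class SchemaError(ValueError):
    """A required column is missing or has the wrong shape."""


class ValidationError(ValueError):
    """Values violate a domain invariant (bounds, consistency)."""


# --------------------------------------------------------------------------
# Panel configuration
# --------------------------------------------------------------------------

ARTIFACT = "artifact"

#: columns every cell table must provide
MANDATORY_COLUMNS = ("cell_id", "x_um", "y_um")

CN2_LABELS = ("tumor", "stroma")
CN3_LABELS = ("tumor", "interface", "stroma")
MBN_LABELS = ("minimal", "low", "medium_regulatory", "high")


@dataclass(frozen=True)
class PhenotypeRule:
    """One gating rule: required-positive and required-negative lineage markers.

    Rules are evaluated in panel order; the first rule whose required-positive
    markers are all positive and required-negative markers all negative
    assigns its cell type.  Markers absent from both sets are unconstrained.
    """

    cell_type: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()


@dataclass
class PanelConfig:
    """Marker roles, phenotype gating rules and the pathway->proxy-marker map."""

    lineage_markers: list[str]
    functional_markers: list[str]
    metabolic_markers: list[str]
    phenotype_rules: list[PhenotypeRule]
    pathway_map: dict[str, str]
    tumor_functional_set: list[str]
    immune_functional_set: list[str]
    artifact_profiles: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pathway_map) != 7:
            raise ValidationError(
                f"pathway_map must have exactly 7 entries, got {len(self.pathway_map)}"
            )
        types = [r.cell_type for r in self.phenotype_rules]
        if len(set(types)) != len(types):
            raise ValidationError("phenotype rule target types must be unique")
        known = set(self.lineage_markers)
        for rule in self.phenotype_rules:
            unknown = (set(rule.positive) | set(rule.negative)) - known
            if unknown:
                raise ValidationError(
                    f"rule for {rule.cell_type!r} references unknown markers {sorted(unknown)}"
                )
        for pw, marker in self.pathway_map.items():
            if marker not in self.metabolic_markers:
                raise ValidationError(
                    f"pathway {pw!r} proxy {marker!r} not in metabolic_markers"
                )

    @property
    def markers(self) -> list[str]:
        """All panel markers, lineage first, no duplicates, stable order."""
        seen: dict[str, None] = {}
        for m in (
            self.lineage_markers + self.functional_markers + self.metabolic_markers
        ):
            seen.setdefault(m)
        return list(seen)

    @property
    def cell_types(self) -> list[str]:
        return [r.cell_type for r in self.phenotype_rules]

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "lineage_markers": self.lineage_markers,
            "functional_markers": self.functional_markers,
            "metabolic_markers": self.metabolic_markers,
            "phenotype_rules": [
                {
                    "cell_type": r.cell_type,
                    "positive": list(r.positive),
                    "negative": list(r.negative),
                }
                for r in self.phenotype_rules
            ],
            "pathway_map": self.pathway_map,
            "tumor_functional_set": self.tumor_functional_set,
            "immune_functional_set": self.immune_functional_set,
            "artifact_profiles": [list(p) for p in self.artifact_profiles],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["phenotype_rules"] = [
            PhenotypeRule(r["cell_type"], tuple(r["positive"]), tuple(r.get("negative", ())))
            for r in payload["phenotype_rules"]
        ]
        payload["artifact_profiles"] = [
            tuple(p) for p in payload.get("artifact_profiles", [])
        ]
        return cls(**payload)


def default_panel() -> PanelConfig:
    """The NSCLC 44-plex-style panel: 14 mutually exclusive lineages, immune and
    tumor functional markers, and 7 metabolic pathway proxy markers.

    Rule order encodes specificity: T-cell subsets and myeloid subsets are
    gated before their CD45+ parents so that every positivity profile maps to
    at most one type; an all-negative profile falls through to ``other``.
    """
    lineage = [
        "PanCK", "ECadherin", "CD45", "CD14", "CD68", "CD31", "CD34",
        "Vimentin", "SMA", "CD3", "CD11b", "CD20", "CD4", "CD8", "FOXP3",
    ]
    functional = ["PD1", "PDL1", "GranzymeB", "ICOS", "IDO1", "Ki67", "HLA-A", "Vimentin"]
    metabolic = ["ASCT2", "ATPA5", "CS", "CPT1A", "G6PD", "GLUT1", "pNRF2"]
    rules = [
        PhenotypeRule("tumor", ("PanCK", "ECadherin"), ("CD45",)),
        PhenotypeRule("macrophage", ("CD45", "CD14", "CD68"), ("CD3", "PanCK")),
        PhenotypeRule("myeloid_nos", ("CD45", "CD14"), ("CD68", "CD3", "PanCK")),
        PhenotypeRule("endothelial", ("CD45", "CD31", "CD34"), ("CD3", "CD14", "PanCK")),
        PhenotypeRule("cd4_treg", ("CD45", "CD3", "CD4", "FOXP3"), ("CD8", "PanCK")),
        PhenotypeRule("cd4_t", ("CD45", "CD3", "CD4"), ("FOXP3", "CD8", "PanCK")),
        PhenotypeRule("cd8_t", ("CD45", "CD3", "CD8"), ("CD4", "PanCK")),
        PhenotypeRule("granulocyte", ("CD45", "CD11b"), ("CD3", "CD14", "CD20", "PanCK")),
        PhenotypeRule("b_cell", ("CD45", "CD20"), ("CD3", "CD14", "PanCK")),
        PhenotypeRule(
            "plasma_cell", ("CD45", "CD31"), ("CD3", "CD20", "CD34", "CD14", "PanCK")
        ),
        PhenotypeRule("myofibroblast", ("CD45", "SMA"), ("CD3", "CD14", "CD31", "PanCK")),
        PhenotypeRule(
            "fibroblast", ("CD45", "Vimentin"), ("CD3", "CD14", "CD31", "SMA", "PanCK")
        ),
        PhenotypeRule(
            "immune_nos", ("CD45",), ("CD3", "CD14", "CD31", "CD20", "CD11b", "SMA",
                                      "Vimentin", "PanCK")
        ),
        PhenotypeRule("other", (), ("CD45", "PanCK", "CD3", "CD14")),
    ]
    pathway_map = {
        "amino_acid_uptake": "ASCT2",
        "atp_synthesis": "ATPA5",
        "tca_cycle": "CS",
        "fatty_acid_oxidation": "CPT1A",
        "ppp": "G6PD",
        "glycolysis": "GLUT1",
        "ox_regulatory": "pNRF2",
    }
    return PanelConfig(
        lineage_markers=lineage,
        functional_markers=functional,
        metabolic_markers=metabolic,
        phenotype_rules=rules,
        pathway_map=pathway_map,
        tumor_functional_set=["PDL1", "Vimentin", "Ki67", "IDO1", "HLA-A"],
        immune_functional_set=["PD1", "PDL1", "GranzymeB", "ICOS", "IDO1"],
        # recurrent implausible co-positivity flagged as staining artifact
        artifact_profiles=[("PanCK", "CD45", "CD3", "CD14")],
    )


# --------------------------------------------------------------------------
# Cell tables
# --------------------------------------------------------------------------

def prob_col(marker: str) -> str:
    return f"{marker}_prob"


def pos_col(marker: str) -> str:
    return f"{marker}_pos"


def validate_cell_table(df: pd.DataFrame, panel: PanelConfig) -> pd.DataFrame:
    """Validate coordinates, probability bounds and marker coverage in place."""
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table missing mandatory column {col!r}")
    for col in ("x_um", "y_um"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() | ~np.isfinite(values)]
        if len(bad):
            raise ValidationError(
                f"non-numeric or non-finite coordinate in column {col!r} "
                f"at row index {bad[0]}"
            )
        df[col] = values.astype(float)
    covered = []
    for marker in panel.markers:
        has_prob = prob_col(marker) in df.columns
        has_pos = pos_col(marker) in df.columns
        if has_prob:
            p = df[prob_col(marker)].to_numpy(dtype=float)
            if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
                raise ValidationError(
                    f"probabilities for marker {marker!r} outside [0, 1]"
                )
        covered.append(has_prob or has_pos)
    if not any(covered):
        raise SchemaError(
            "cell table provides neither probability nor positivity columns "
            "for any panel marker"
        )
    return df


def read_cell_table(path, panel: PanelConfig) -> pd.DataFrame:
    """Read a per-cell CSV, normalizing lenient column spellings.

    ``x``/``y`` are accepted for ``x_um``/``y_um``; a bare ``<marker>`` column
    is interpreted as a probability when it contains non-binary values and as
    a binary call otherwise.  ``cell_id`` is generated from the row order when
    absent.  Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path)
    rename = {}
    if "x_um" not in df.columns and "x" in df.columns:
        rename["x"] = "x_um"
    if "y_um" not in df.columns and "y" in df.columns:
        rename["y"] = "y_um"
    df = df.rename(columns=rename)
    for marker in panel.markers:
        if marker in df.columns and prob_col(marker) not in df.columns:
            values = pd.to_numeric(df[marker], errors="coerce")
            if values.dropna().isin([0, 1]).all():
                df[pos_col(marker)] = values.astype(bool)
            else:
                df[prob_col(marker)] = values
            df = df.drop(columns=[marker])
    if "cell_id" not in df.columns:
        df["cell_id"] = np.arange(len(df))
    if "core_id" not in df.columns:
        df["core_id"] = "core0"
    if "patient_id" not in df.columns:
        df["patient_id"] = df["core_id"]
    return validate_cell_table(df, panel)


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def split_cores(cells: pd.DataFrame):
    """Yield ``(core_id, per-core frame)`` in stable core order."""
    for core_id, sub in cells.groupby("core_id", sort=True):
        yield core_id, sub


# --------------------------------------------------------------------------
# Clinical table
# --------------------------------------------------------------------------

BOR_LEVELS = ("CR", "PR", "SD", "PD")

CLINICAL_COLUMNS = (
    "patient_id", "cohort_id", "pfs_time", "pfs_event", "os_time", "os_event", "bor"
)


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("patient_id", "pfs_time", "pfs_event"):
        if col not in df.columns:
            raise SchemaError(f"clinical table missing mandatory column {col!r}")
    for col in ("pfs_time", "os_time"):
        if col in df.columns and (df[col] <= 0).any():
            raise ValidationError(f"{col} must be strictly positive")
    if "bor" in df.columns:
        bad = set(df["bor"].dropna()) - set(BOR_LEVELS)
        if bad:
            raise ValidationError(f"unknown BOR categories {sorted(bad)}")
    return df


def read_clinical_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("pfs_event", "os_event", "cb6"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return validate_clinical_table(df)


def write_clinical_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def derive_cb6(clinical: pd.DataFrame) -> pd.DataFrame:
    """Clinical benefit at 6 months: objective response (CR/PR) or PFS > 6 months.

    Progression at exactly 6 months counts as no benefit (strict inequality).
    Patients with neither a BOR category nor a PFS time cannot be classified.
    """
    clinical = validate_clinical_table(clinical).copy()
    bor = clinical["bor"] if "bor" in clinical.columns else pd.Series(
        [None] * len(clinical), index=clinical.index
    )
    undefined = bor.isna() & clinical["pfs_time"].isna()
    if undefined.any():
        pid = clinical.loc[undefined, "patient_id"].iloc[0]
        raise ValidationError(f"cb6 undefined for patient {pid!r}: no BOR and no PFS")
    objective = bor.isin(["CR", "PR"]).fillna(False)
    beyond6 = (clinical["pfs_time"] > 6.0).fillna(False)
    clinical["cb6"] = (objective | beyond6).astype(bool)
    return clinical
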