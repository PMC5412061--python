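"""Internal-standard quantification, stochastic-sampling QC, and the
log10 feature matrix.

Transcript abundance is the NT/IS read ratio scaled by the known IS
spike-in copies, reported per 1e6 reference-gene (ACTB) molecules. A
closed-form coefficient of variation predicted from molecules loaded and
reads obtained gates every measurement; cells with CV >= 1.0 are missing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

AVOGADRO = 6.022e23  # mol^-1, at the precision the reagent math uses

MEASURED = "measured"
FILTERED = "filtered_low_confidence"
ABSENT = "absent"

DEMOGRAPHIC_FEATURES = ("age", "gender", "pack_years")


def copies_per_microliter(molar: float, round_to: Optional[int] = 100) -> float:
    """Copies/uL of a solution at the given molarity (mol/L).

    A 1e-15 M (1 fM) solution carries ~600 copies/uL; 1e-14 M ~6000.
    """
    copies = molar * AVOGADRO / 1e6
    if round_to:
        copies = round(copies / round_to) * round_to
    return copies


# ---------------------------------------------------------------------------
# per-cell quantities
# ---------------------------------------------------------------------------

def molecules_from_counts(nt_reads: float, is_reads: float,
                          is_input_copies: float) -> Optional[float]:
    """Starting NT copy number: IS input copies x (NT reads / IS reads).

    Returns None (missing) when there are no IS reads to anchor the ratio.
    """
    if is_reads <= 0:
        return None
    return is_input_copies * nt_reads / is_reads


def abundance_per_million_actb(target_molecules: float,
                               actb_molecules: float) -> float:
    """Target molecules per 1e6 reference molecules."""
    if actb_molecules <= 0:
        raise ValueError("reference molecule count must be positive")
    return target_molecules / actb_molecules * 1e6


def stochastic_cv(molecules_input: float, sequence_reads: float,
                  exponent: float = -0.54) -> float:
    """Predicted sampling CV from molecules loaded and reads obtained.

        CV = -1 + 10**(M**-0.54 + R**-0.54 - (M*R)**-0.54)

    Strictly decreasing in each argument (for the other > 1) and -> 0 as
    both grow. Non-positive arguments are undefined (raises).
    """
    if molecules_input <= 0 or sequence_reads <= 0:
        raise ValueError("stochastic CV undefined for non-positive arguments")
    m, r = float(molecules_input), float(sequence_reads)
    return -1.0 + 10.0 ** (m ** exponent + r ** exponent
                           - (m * r) ** exponent)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    cv_threshold: float = 1.0
    min_is_reads: int = 10
    # which quantities feed the CV formula; NT molecules are the scarce
    # quantity driving stochastic sampling, total reads bound precision
    molecules_arg: str = "nt_molecules"   # or "is_input"
    reads_arg: str = "total_reads"        # or "nt_reads"


def apply_measurement_filter(counts: pd.DataFrame, design: pd.DataFrame,
                             thresholds: Optional[QCThresholds] = None
                             ) -> pd.DataFrame:
    """Per-cell molecule estimate, predicted CV, and pass flag.

    A cell passes iff its CV is defined and < cv_threshold and it has at
    least ``min_is_reads`` IS reads. Failed cells are missing downstream.
    """
    thr = thresholds or QCThresholds()
    des = design.set_index("assay_id")
    rows = []
    for row in counts.itertuples(index=False):
        is_input = des.at[row.assay_id, "is_input_copies"]
        molecules = molecules_from_counts(row.nt_reads, row.is_reads, is_input)
        total_reads = row.nt_reads + row.is_reads
        if thr.molecules_arg == "nt_molecules":
            m_arg = molecules
        else:
            m_arg = float(is_input)
        r_arg = total_reads if thr.reads_arg == "total_reads" else row.nt_reads
        cv = math.nan
        ok = False
        if molecules is not None and m_arg is not None and m_arg > 0 and r_arg > 0:
            cv = stochastic_cv(m_arg, r_arg)
            ok = cv < thr.cv_threshold and row.is_reads >= thr.min_is_reads
        rows.append({"subject_id": row.subject_id, "assay_id": row.assay_id,
                     "molecules": math.nan if molecules is None else molecules,
                     "total_reads": total_reads, "cv": cv, "pass": ok})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Subjects x features with a provenance mask.

    ``values`` holds gene features (abundance, later log10) and the
    demographic features age / gender (1 = M) / pack_years; ``provenance``
    marks every gene cell measured / filtered_low_confidence / absent.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    labels: pd.Series
    gene_features: list[str] = field(default_factory=list)
    filter_log: dict = field(default_factory=dict)

    @property
    def demographic_features(self) -> list[str]:
        return [c for c in self.values.columns if c not in self.gene_features]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.provenance.copy(),
                               self.labels.copy(), list(self.gene_features),
                               dict(self.filter_log))

    def write(self, values_path, provenance_path=None, log_path=None) -> None:
        out = self.values.copy()
        out.insert(0, "class_label", self.labels)
        out.to_csv(values_path, sep="\t", na_rep="NA")
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, sep="\t")
        if log_path is not None:
            Path(log_path).write_text(json.dumps(self.filter_log, indent=2))

    @classmethod
    def read(cls, values_path, provenance_path=None) -> "AbundanceMatrix":
        df = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA"])
        labels = df.pop("class_label")
        genes = [c for c in df.columns if c not in DEMOGRAPHIC_FEATURES]
        if provenance_path is not None and Path(provenance_path).exists():
            prov = pd.read_csv(provenance_path, sep="\t", index_col=0)
        else:
            prov = pd.DataFrame(np.where(df[genes].isna(), ABSENT, MEASURED),
                                index=df.index, columns=genes)
        return cls(df, prov, labels, genes)


def build_abundance_matrix(counts: pd.DataFrame, design: pd.DataFrame,
                           subjects: pd.DataFrame,
                           thresholds: Optional[QCThresholds] = None,
                           qc: Optional[pd.DataFrame] = None
                           ) -> AbundanceMatrix:
    """Counts -> molecules -> per-1e6-ACTB abundance with QC masking.

    The reference (ACTB) assay must itself pass QC; if it fails, every
    gene measurement for that subject is unusable and marked absent.
    """
    thr = thresholds or QCThresholds()
    if qc is None:
        qc = apply_measurement_filter(counts, design, thr)
    ref_assays = design.loc[design["is_reference_assay"], "assay_id"].tolist()
    if len(ref_assays) != 1:
        raise ValueError("manifest must flag exactly one reference assay")
    ref_assay = ref_assays[0]
    target_assays = [a for a in design["assay_id"] if a != ref_assay]

    qc_idx = qc.set_index(["subject_id", "assay_id"])
    subject_ids = subjects["subject_id"].tolist()
    values = pd.DataFrame(np.nan, index=subject_ids, columns=target_assays)
    prov = pd.DataFrame(ABSENT, index=subject_ids, columns=target_assays)

    for sid in subject_ids:
        try:
            ref_cell = qc_idx.loc[(sid, ref_assay)]
        except KeyError:
            continue
        ref_ok = bool(ref_cell["pass"]) and ref_cell["molecules"] > 0
        for assay in target_assays:
            try:
                cell = qc_idx.loc[(sid, assay)]
            except KeyError:
                continue
            if not ref_ok:
                prov.at[sid, assay] = ABSENT
                continue
            if not cell["pass"]:
                prov.at[sid, assay] = FILTERED
                continue
            values.at[sid, assay] = abundance_per_million_actb(
                cell["molecules"], ref_cell["molecules"])
            prov.at[sid, assay] = MEASURED

    sub = subjects.set_index("subject_id").reindex(subject_ids)
    values["age"] = sub["age"].astype(float)
    values["gender"] = sub["gender"].map({"M": 1.0, "F": 0.0})
    values["pack_years"] = sub["pack_years"].astype(float)
    labels = sub["class_label"]
    values.index.name = "subject_id"
    return AbundanceMatrix(values, prov, labels, target_assays,
                           {"reference_assay": ref_assay})


def filter_assays(matrix: AbundanceMatrix,
                  max_missing_frac: float = 0.30) -> AbundanceMatrix:
    """Drop gene features whose missing fraction strictly exceeds the cap.

    Demographic features are never dropped here. Idempotent.
    """
    if matrix.values.shape[0] < 1:
        raise ValueError("matrix has no subjects")
    frac = matrix.values[matrix.gene_features].isna().mean()
    removed = frac.index[frac > max_missing_frac].tolist()
    kept = [g for g in matrix.gene_features if g not in removed]
    out = matrix.copy()
    out.values = matrix.values.drop(columns=removed)
    out.provenance = matrix.provenance.drop(columns=removed)
    out.gene_features = kept
    out.filter_log = dict(matrix.filter_log)
    out.filter_log["assays_removed"] = removed
    out.filter_log["assay_missing_fraction"] = {
        k: float(v) for k, v in frac.items()}
    return out


def filter_subjects(matrix: AbundanceMatrix,
                    min_assays: int = 6) -> AbundanceMatrix:
    """Drop subjects with fewer than ``min_assays`` measured gene features."""
    n_measured = matrix.values[matrix.gene_features].notna().sum(axis=1)
    keep = n_measured >= min_assays
    if not keep.any():
        raise ValueError("all subjects removed by the per-subject filter")
    out = matrix.copy()
    out.values = matrix.values.loc[keep]
    out.provenance = matrix.provenance.loc[keep]
    out.labels = matrix.labels.loc[keep]
    out.filter_log = dict(matrix.filter_log)
    out.filter_log["subjects_removed"] = matrix.values.index[~keep].tolist()
    return out


def log10_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log10 of gene abundances; zeros become missing, demographics untouched."""
    genes = matrix.gene_features
    vals = matrix.values[genes]
    if (vals < 0).any().any():
        raise ValueError("negative abundance encountered")
    out = matrix.copy()
    zero = vals == 0
    with np.errstate(divide="ignore"):
        out.values[genes] = np.log10(vals.where(~zero))
    out.provenance = matrix.provenance.mask(
        zero.reindex(columns=matrix.provenance.columns, fill_value=False),
        FILTERED)
    out.filter_log = dict(matrix.filter_log)
    out.filter_log["log10"] = True
    return out
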