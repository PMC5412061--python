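"""Synthetic cohort and competitive-amplicon read simulator.

Generates subjects with demographics and dual barcodes, per-assay true
transcript abundances (molecules per 1e6 reference-gene molecules) from a
latent-factor Gaussian model on the log10 scale, molecule/read tallies under
Poisson molecule sampling and binomial read splitting, and optionally paired
FASTQ files in a fixed joined-read layout::

    [barcode_f][primer_f][captured region][revcomp(primer_r)][revcomp(barcode_r)]

The captured region is either the native template (NT) or the internal
standard (IS) sequence; the two differ at exactly six positions.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REFERENCE_GENE = "ACTB"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_demographics() -> dict:
    # Per-class age (years), male fraction, pack-years; values chosen to
    # resemble a retrospective case/control bronchoscopy cohort.
    return {
        "NC": {"age_mean": 59.3, "age_sd": 14.2, "male_frac": 28 / 57,
               "pack_years_mean": 43.0, "pack_years_sd": 28.7},
        "CA": {"age_mean": 64.4, "age_sd": 9.5, "male_frac": 40 / 56,
               "pack_years_mean": 53.0, "pack_years_sd": 31.3},
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort generator.

    The same seed always produces byte-identical outputs.
    """

    n_subjects_cancer: int = 58
    n_subjects_control: int = 57
    n_assays: int = 68
    n_genes: int = 33
    n_informative_assays: int = 13
    effect_size_log10: float = 0.5
    latent_factors: int = 3
    loading_scale: float = 0.2
    residual_sd: float = 0.3
    baseline_log10_min: float = 1.6
    baseline_log10_max: float = 5.0
    actb_molecules_mean: float = 30000.0
    actb_molecules_cv: float = 0.5
    depth_mean: float = 2000.0
    depth_cv: float = 0.5
    base_error_rate: float = 0.001
    is_input_copies: int = 600
    actb_is_input_copies: int = 6000
    is_poisson_jitter: bool = False
    barcode_length: int = 8
    primer_length: int = 20
    amplicon_length: int = 101
    n_is_diff_positions: int = 6
    demographic_params: dict = field(default_factory=_default_demographics)
    demographic_missing_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_cancer <= 0 or self.n_subjects_control <= 0:
            raise ValueError("class sizes must be positive")
        for name in ("n_assays", "n_genes", "latent_factors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_informative_assays <= self.n_assays:
            raise ValueError("n_informative_assays must be in [0, n_assays]")
        for name in ("base_error_rate", "demographic_missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.captured_length < self.n_is_diff_positions:
            raise ValueError("captured region shorter than IS-difference count")

    @property
    def captured_length(self) -> int:
        return self.amplicon_length - 2 * self.primer_length

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream for one simulation stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth backing parameter-recovery tests.

    abundance: subjects x assays, molecules per 1e6 ACTB (linear scale).
    actb_per_ul: per-subject reference-gene molecules in a 1-uL aliquot.
    assay_info: per assay: gene, informative flag, effect direction.
    """

    abundance: pd.DataFrame
    actb_per_ul: pd.Series
    assay_info: pd.DataFrame


# ---------------------------------------------------------------------------
# sequence pools
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=length))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _distinct_pool(rng: np.random.Generator, n: int, length: int,
                   min_dist: int) -> list[str]:
    """Greedy pool of sequences with pairwise Hamming distance >= min_dist.

    When the greedy search stalls (pool capacity at this distance is
    exhausted) the distance requirement is relaxed stepwise down to plain
    uniqueness, so very large simulated cohorts remain generable.
    """
    if 4 ** length < n:
        raise RuntimeError(f"cannot build {n} distinct {length}-mers")
    pool: list[str] = []
    arr = np.empty((0, length), dtype=np.uint8)
    stall = 0
    while len(pool) < n:
        cand = _random_seq(rng, length)
        cvec = np.frombuffer(cand.encode(), dtype=np.uint8)
        if arr.size == 0 or (arr != cvec).sum(axis=1).min() >= min_dist:
            pool.append(cand)
            arr = np.vstack([arr, cvec])
            stall = 0
            continue
        stall += 1
        if stall > 200 + 20 * n and min_dist > 1:
            min_dist -= 1
            stall = 0
    return pool


def generate_design(config: SimConfig) -> pd.DataFrame:
    """Assay manifest: primers, NT/IS captured sequences, IS input copies.

    One assay is flagged as the reference (ACTB) assay and carries the
    higher IS spike-in. NT and IS captured sequences differ at exactly
    ``config.n_is_diff_positions`` positions.
    """
    config.validate()
    rng = config.rng(0)
    n = config.n_assays
    primers = _distinct_pool(rng, 2 * n, config.primer_length, min_dist=6)
    genes = [REFERENCE_GENE] + [f"G{i:02d}" for i in range(2, config.n_genes + 1)]
    rows = []
    cap_len = config.captured_length
    for i in range(n):
        gene = genes[i % config.n_genes]
        is_ref = gene == REFERENCE_GENE and i < config.n_genes
        nt = _random_seq(rng, cap_len)
        pos = rng.choice(cap_len, size=config.n_is_diff_positions, replace=False)
        is_seq = list(nt)
        for p in pos:
            alternatives = [b for b in DNA_BASES if b != nt[p]]
            is_seq[p] = alternatives[rng.integers(len(alternatives))]
        rows.append({
            "assay_id": f"{gene}_a{i + 1:02d}",
            "gene": gene,
            "primer_f": primers[2 * i],
            "primer_r": primers[2 * i + 1],
            "nt_captured": nt,
            "is_captured": "".join(is_seq),
            "is_input_copies": (config.actb_is_input_copies if is_ref
                                else config.is_input_copies),
            "is_reference_assay": is_ref,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig,
                    design: Optional[pd.DataFrame] = None
                    ) -> tuple[pd.DataFrame, TruthTable]:
    """Draw subjects (demographics + barcodes) and true abundances.

    log10 abundance of assay j in subject i is

        baseline_j + direction_j * effect * 1{class_i == CA, j informative}
        + loadings_j . factors_i + noise_ij

    The reference assay is pinned at 1e6 molecules per 1e6 ACTB by
    definition; per-subject ACTB input molecules are lognormal.
    """
    config.validate()
    if design is None:
        design = generate_design(config)
    rng = config.rng(1)

    n_ca, n_nc = config.n_subjects_cancer, config.n_subjects_control
    n_sub = n_ca + n_nc
    labels = np.array(["CA"] * n_ca + ["NC"] * n_nc)
    subject_ids = [f"S{i + 1:03d}" for i in range(n_sub)]

    bc_f = _distinct_pool(rng, n_sub, config.barcode_length, min_dist=3)
    bc_r = _distinct_pool(rng, n_sub, config.barcode_length, min_dist=3)

    demo_rows = []
    for i, lab in enumerate(labels):
        p = config.demographic_params[lab]
        age = rng.normal(p["age_mean"], p["age_sd"])
        gender = "M" if rng.random() < p["male_frac"] else "F"
        pack = max(0.0, rng.normal(p["pack_years_mean"], p["pack_years_sd"]))
        demo_rows.append({
            "subject_id": subject_ids[i], "class_label": lab,
            "age": age, "gender": gender, "pack_years": pack,
            "barcode_f": bc_f[i], "barcode_r": bc_r[i],
        })
    subjects = pd.DataFrame(demo_rows)
    for col in ("age", "gender", "pack_years"):
        mask = rng.random(n_sub) < config.demographic_missing_rate
        subjects.loc[mask, col] = np.nan

    assay_ids = design["assay_id"].tolist()
    ref_mask = design["is_reference_assay"].to_numpy(bool)
    n_assay = len(assay_ids)

    baselines = rng.uniform(config.baseline_log10_min,
                            config.baseline_log10_max, size=n_assay)
    # informative assays chosen among the better-expressed half so the class
    # signal survives downstream low-count filtering
    candidates = np.where(~ref_mask)[0]
    order = candidates[np.argsort(-baselines[candidates])]
    top_half = order[: max(config.n_informative_assays,
                           len(candidates) // 2)]
    informative_idx = rng.choice(top_half, size=config.n_informative_assays,
                                 replace=False)
    informative = np.zeros(n_assay, bool)
    informative[informative_idx] = True
    direction = np.zeros(n_assay, int)
    direction[informative_idx] = np.where(
        np.arange(config.n_informative_assays) % 2 == 0, 1, -1)

    loadings = rng.normal(0.0, config.loading_scale,
                          size=(n_assay, config.latent_factors))
    factors = rng.normal(size=(n_sub, config.latent_factors))
    noise = rng.normal(0.0, config.residual_sd, size=(n_sub, n_assay))
    shift = np.outer(labels == "CA", direction * config.effect_size_log10)
    log10_abund = baselines[None, :] + shift + factors @ loadings.T + noise
    abundance = 10.0 ** log10_abund
    abundance[:, ref_mask] = 1e6  # reference abundance is definitional

    sigma = math.sqrt(math.log(1.0 + config.actb_molecules_cv ** 2))
    mu = math.log(config.actb_molecules_mean) - 0.5 * sigma ** 2
    actb = pd.Series(rng.lognormal(mu, sigma, size=n_sub),
                     index=subject_ids, name="actb_per_ul")

    truth = TruthTable(
        abundance=pd.DataFrame(abundance, index=subject_ids, columns=assay_ids),
        actb_per_ul=actb,
        assay_info=pd.DataFrame({
            "assay_id": assay_ids, "gene": design["gene"].to_numpy(),
            "informative": informative, "effect_direction": direction,
        }).set_index("assay_id"),
    )
    return subjects, truth


# ---------------------------------------------------------------------------
# molecule / read simulation
# ---------------------------------------------------------------------------

def simulate_counts(truth: TruthTable, subjects: pd.DataFrame,
                    design: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Poisson molecule sampling + binomial read splitting.

    nt_molecules ~ Poisson(true_abundance * actb_per_ul / 1e6) for a 1-uL
    aliquot; is_molecules is the fixed spike-in copy number (optionally
    Poisson-jittered); total reads per assay-cell are lognormal; NT reads
    are binomial with probability nt/(nt+is) — the equal-efficiency
    competitive model.
    """
    if list(truth.abundance.columns) != list(design["assay_id"]):
        raise ValueError("truth table and design cover different assays")
    rng = config.rng(2)
    subject_ids = truth.abundance.index.to_numpy()
    n_sub, n_assay = truth.abundance.shape

    lam = truth.abundance.to_numpy() * truth.actb_per_ul.to_numpy()[:, None] / 1e6
    nt_mol = rng.poisson(lam)
    is_input = design["is_input_copies"].to_numpy()
    if config.is_poisson_jitter:
        is_mol = rng.poisson(np.broadcast_to(is_input, (n_sub, n_assay)))
    else:
        is_mol = np.broadcast_to(is_input, (n_sub, n_assay)).copy()

    sigma = math.sqrt(math.log(1.0 + config.depth_cv ** 2))
    mu = math.log(config.depth_mean) - 0.5 * sigma ** 2
    depth = np.rint(rng.lognormal(mu, sigma, size=(n_sub, n_assay))).astype(int)
    depth = np.maximum(depth, 0)

    tot_mol = nt_mol + is_mol
    with np.errstate(invalid="ignore", divide="ignore"):
        p_nt = np.where(tot_mol > 0, nt_mol / np.maximum(tot_mol, 1), 0.0)
    nt_reads = rng.binomial(np.where(tot_mol > 0, depth, 0), p_nt)
    is_reads = np.where(tot_mol > 0, depth, 0) - nt_reads

    idx = pd.MultiIndex.from_product([subject_ids, truth.abundance.columns],
                                     names=["subject_id", "assay_id"])
    return pd.DataFrame({
        "nt_molecules": nt_mol.ravel(),
        "is_molecules": is_mol.ravel(),
        "nt_reads": nt_reads.ravel(),
        "is_reads": is_reads.ravel(),
    }, index=idx).reset_index()


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def _open_text(path, mode="wt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, max(2, round(-10 * math.log10(error_rate))))
    return chr(q + 33)


def emit_fastq(tally: pd.DataFrame, subjects: pd.DataFrame,
               design: pd.DataFrame, config: SimConfig,
               path_r1, path_r2) -> int:
    """Write paired FASTQ for every NT/IS read in the tally.

    Read 1 is the 5' half of the joined amplicon; read 2 is the reverse
    complement of the 3' half (non-overlapping split). Substitution errors
    are injected uniformly at ``base_error_rate``; qualities are constant
    and consistent with that rate. Returns the number of read pairs written.
    """
    rng = config.rng(3)
    sub = subjects.set_index("subject_id")
    des = design.set_index("assay_id")
    missing = set(tally["subject_id"]) - set(sub.index)
    if missing:
        raise ValueError(f"no barcode assignment for subjects: {sorted(missing)[:5]}")

    templates = []  # (full joined sequence) per read
    for row in tally.itertuples(index=False):
        srow = sub.loc[row.subject_id]
        drow = des.loc[row.assay_id]
        core_nt = (srow.barcode_f + drow.primer_f + drow.nt_captured
                   + revcomp(drow.primer_r) + revcomp(srow.barcode_r))
        core_is = (srow.barcode_f + drow.primer_f + drow.is_captured
                   + revcomp(drow.primer_r) + revcomp(srow.barcode_r))
        templates.extend([core_nt] * int(row.nt_reads))
        templates.extend([core_is] * int(row.is_reads))

    order = rng.permutation(len(templates))
    qual = _phred_char(config.base_error_rate)
    err = config.base_error_rate
    n_written = 0
    with _open_text(path_r1) as f1, _open_text(path_r2) as f2:
        for k in order:
            full = templates[k]
            if err > 0:
                seq = list(full)
                hits = np.nonzero(rng.random(len(seq)) < err)[0]
                for p in hits:
                    alternatives = [b for b in DNA_BASES if b != seq[p]]
                    seq[p] = alternatives[rng.integers(3)]
                full = "".join(seq)
            half = len(full) // 2
            r1, r2 = full[:half], revcomp(full[half:])
            n_written += 1
            name = f"read{n_written}"
            f1.write(f"@{name}/1\n{r1}\n+\n{qual * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{qual * len(r2)}\n")
    return n_written


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_sample_sheet(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_truth(truth: TruthTable, path) -> None:
    long = truth.abundance.stack().rename("true_abundance").reset_index()
    long.columns = ["subject_id", "assay_id", "true_abundance"]
    long = long.merge(truth.assay_info.reset_index(), on="assay_id")
    long["actb_per_ul"] = truth.actb_per_ul.reindex(long["subject_id"]).to_numpy()
    long.to_csv(path, sep="\t", index=False)


def write_tally(tally: pd.DataFrame, path) -> None:
    tally.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"assay_id": str, "gene": str})
    df["is_reference_assay"] = df["is_reference_assay"].astype(bool)
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       dtype={"subject_id": str, "class_label": str,
                              "gender": str, "barcode_f": str, "barcode_r": str})
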