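"""Synthetic two-sample MR summary statistics with known ground truth.

The generator emulates the structure of an educational-attainment exposure
GWAS paired with several Alzheimer's-disease outcome datasets — a
clinically diagnosed GWAS and family-history proxy (GWAX) studies.  For
variant j with true instrument effect gamma_j ~ N(0, gamma_sd^2):

    beta_x_j   = gamma_j + N(0, se_x_j^2)
    beta_y_d_j = lambda_d * theta_d * gamma_j
                 + alpha_j * [j pleiotropic]
                 + b_{d,j} + N(0, se_y_d_j^2),   b_{d,j} ~ N(0, tau^2)

where theta_d is the dataset's causal slope (log-odds per exposure SD),
lambda_d a multiplicative proxy-dilution factor, alpha_j directional
pleiotropy and tau the per-variant between-dataset heterogeneity SD.
SEs are drawn uniformly from configured ranges; p-values come from normal
Wald tests.  All draws pass through substreams named by purpose and rsid,
so any one component can be regenerated independently of the others.

The default configuration mirrors the published study conditions: 143
shared instruments, exposure effects of a few hundredths of an SD with
the precision of a ~400k-sample GWAS, and per-dataset slopes equal to the
average Wald estimators reported for the clinical GWAS (-0.34... see
docs/methods.md), the 2018 proxy study (+0.13) and the 2021 proxy study
(+0.65).
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field

import numpy as np

from .harmonize import HarmonizedPanel, HarmonizedVariant
from .summary_io import SummaryDataset, VariantAssociation

NON_PALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
)
PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _default_thetas() -> dict[str, float]:
    return {"GWAS": -0.34, "GWAX2018": 0.13, "GWAX2021": 0.65}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_variants: int = 143
    gamma_sd: float = 0.025         # SD of true instrument effects (exposure SD units)
    se_x_range: tuple[float, float] = (0.0025, 0.0045)
    se_y_range: tuple[float, float] = (0.015, 0.035)
    theta_by_dataset: dict[str, float] = field(default_factory=_default_thetas)
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    dilution: dict[str, float] = field(default_factory=dict)  # lambda_d, default 1
    tau: float = 0.0                # between-dataset per-variant heterogeneity SD
    noise_scale: float = 1.0        # multiplier on sampling noise (0 = exact betas)
    #: condition each instrument on genome-wide significance in the exposure,
    #: emulating a published (already-selected) instrument list; None disables
    select_p_threshold: float | None = 5e-8
    allele_swap_fraction: float = 0.0   # outcome rows listing alleles swapped
    strand_flip_fraction: float = 0.0   # outcome rows reported on the other strand
    palindromic_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 3:
            raise ValueError("need at least three variants")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ValueError("pleiotropy_fraction outside [0, 1]")
        for name in ("gamma_sd", "pleiotropy_sd", "tau", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for lo, hi in (self.se_x_range, self.se_y_range):
            if not (0 < lo <= hi):
                raise ValueError("SE ranges must be positive and ordered")


@dataclass
class SimulatedStudy:
    exposure: SummaryDataset
    outcomes: dict[str, SummaryDataset]
    truth: dict
    config: SimulationConfig

    def panel(self, label: str) -> HarmonizedPanel:
        """Ground-truth-aligned panel for one outcome (no allele logic)."""
        t = self.truth
        out = self.outcomes[label]
        panel = HarmonizedPanel(exposure_label=self.exposure.label, outcome_label=label)
        for j, rsid in enumerate(t["rsids"]):
            exp = self.exposure.records[rsid]
            sign = -1.0 if t["swapped"][label][j] else 1.0
            panel.variants.append(
                HarmonizedVariant(
                    rsid=rsid,
                    beta_x=exp.beta,
                    se_x=exp.se,
                    beta_y=sign * out.records[rsid].beta,
                    se_y=out.records[rsid].se,
                    flipped=bool(t["swapped"][label][j]),
                )
            )
        return panel


def _stream(seed: int, *names) -> np.random.Generator:
    keys = [int(seed)] + [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


def _normal_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(beta) / se
    return np.clip(2 * stats.norm.sf(z), 1e-300, 1.0)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    config.validate()
    config = copy.deepcopy(config)
    J = config.n_variants
    seed = config.seed
    rsids = [f"rs{100001 + j}" for j in range(J)]

    rng_alleles = _stream(seed, "alleles")
    n_pal = int(round(config.palindromic_fraction * J))
    pairs = [
        PALINDROMIC_PAIRS[rng_alleles.integers(len(PALINDROMIC_PAIRS))]
        if j < n_pal
        else NON_PALINDROMIC_PAIRS[rng_alleles.integers(len(NON_PALINDROMIC_PAIRS))]
        for j in range(J)
    ]
    eaf = _stream(seed, "eaf").uniform(0.05, 0.95, size=J)
    # keep palindromic frequencies away from 0.5 so orientation is inferable
    eaf[:n_pal] = np.where(
        eaf[:n_pal] < 0.5,
        np.clip(eaf[:n_pal], 0.05, 0.40),
        np.clip(eaf[:n_pal], 0.60, 0.95),
    )

    se_x = _stream(seed, "se_x").uniform(*config.se_x_range, size=J)
    rng_g = _stream(seed, "gamma")
    rng_nx = _stream(seed, "noise_x")
    gamma = rng_g.normal(0.0, config.gamma_sd, size=J)
    beta_x = gamma + config.noise_scale * rng_nx.normal(0, 1, J) * se_x
    if config.select_p_threshold is not None:
        from scipy import stats

        z_min = float(stats.norm.isf(config.select_p_threshold / 2))
        # redraw sub-threshold instruments: the panel represents a published
        # list, every member of which reached significance in its source GWAS
        weak = np.abs(beta_x) / se_x < z_min
        while np.any(weak):
            k = int(np.sum(weak))
            gamma[weak] = rng_g.normal(0.0, config.gamma_sd, size=k)
            beta_x[weak] = gamma[weak] + config.noise_scale * rng_nx.normal(0, 1, k) * se_x[weak]
            weak = np.abs(beta_x) / se_x < z_min

    n_pleio = int(round(config.pleiotropy_fraction * J))
    pleio_idx = np.zeros(J, dtype=bool)
    pleio_idx[_stream(seed, "pleio_pick").choice(J, size=n_pleio, replace=False)] = True
    alpha = np.where(
        pleio_idx,
        _stream(seed, "pleio_effect").normal(config.pleiotropy_mean, config.pleiotropy_sd, J),
        0.0,
    )

    exposure = SummaryDataset(label="EduYears", trait_type="exposure")
    p_x = _normal_p(beta_x, se_x)
    for j, rsid in enumerate(rsids):
        exposure.records[rsid] = VariantAssociation(
            rsid=rsid,
            effect_allele=pairs[j][0],
            other_allele=pairs[j][1],
            beta=float(beta_x[j]),
            se=float(se_x[j]),
            pvalue=float(p_x[j]),
            eaf=float(eaf[j]),
        )

    outcomes: dict[str, SummaryDataset] = {}
    b_het: dict[str, np.ndarray] = {}
    swapped: dict[str, np.ndarray] = {}
    strand: dict[str, np.ndarray] = {}
    for label, theta in config.theta_by_dataset.items():
        lam = config.dilution.get(label, 1.0)
        se_y = _stream(seed, "se_y", label).uniform(*config.se_y_range, size=J)
        b = _stream(seed, "tau", label).normal(0, 1, J) * config.tau
        # pleiotropy is directional per exposure-increasing allele (the
        # orientation in which the Egger intercept is defined), so its sign
        # follows the instrument's
        beta_y = (
            lam * theta * gamma
            + alpha * np.sign(gamma)
            + b
            + config.noise_scale * _stream(seed, "noise_y", label).normal(0, 1, J) * se_y
        )
        rng_rep = _stream(seed, "report", label)
        swap = rng_rep.random(J) < config.allele_swap_fraction
        flip = rng_rep.random(J) < config.strand_flip_fraction
        flip &= ~np.array([p in PALINDROMIC_PAIRS for p in pairs])  # flips unreadable on palindromes
        ds = SummaryDataset(label=label, trait_type="outcome")
        p_y = _normal_p(beta_y, se_y)
        for j, rsid in enumerate(rsids):
            ea, oa = pairs[j]
            beta_rep, eaf_rep = beta_y[j], eaf[j]
            if swap[j]:
                ea, oa = oa, ea
                beta_rep = -beta_rep
                eaf_rep = 1.0 - eaf_rep
            if flip[j]:
                ea, oa = _COMP[ea], _COMP[oa]
            ds.records[rsid] = VariantAssociation(
                rsid=rsid,
                effect_allele=ea,
                other_allele=oa,
                beta=float(beta_rep),
                se=float(se_y[j]),
                pvalue=float(p_y[j]),
                eaf=float(eaf_rep),
            )
        outcomes[label] = ds
        b_het[label], swapped[label], strand[label] = b, swap, flip

    truth = {
        "rsids": rsids,
        "gamma": gamma,
        "alpha": alpha,
        "pleiotropic": pleio_idx,
        "b": b_het,
        "swapped": swapped,
        "strand_flipped": strand,
        "injected_outliers": {label: [] for label in outcomes},
    }
    return SimulatedStudy(exposure=exposure, outcomes=outcomes, truth=truth, config=config)


def inject_outlier(
    study: SimulatedStudy, dataset: str, rsid: str, shift_in_se: float
) -> SimulatedStudy:
    """Return a copy with one outcome effect shifted by shift_in_se * se_y."""
    if dataset not in study.outcomes:
        raise KeyError(f"unknown dataset {dataset!r}")
    if rsid not in study.outcomes[dataset].records:
        raise KeyError(f"unknown rsid {rsid!r}")
    new = SimulatedStudy(
        exposure=study.exposure,
        outcomes=copy.deepcopy(study.outcomes),
        truth=copy.deepcopy(study.truth),
        config=study.config,
    )
    rec = new.outcomes[dataset].records[rsid]
    j = new.truth["rsids"].index(rsid)
    sign = -1.0 if new.truth["swapped"][dataset][j] else 1.0
    rec.beta += sign * shift_in_se * rec.se  # shift on the harmonized orientation
    if shift_in_se != 0:
        new.truth["injected_outliers"][dataset].append((rsid, shift_in_se))
    return new
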