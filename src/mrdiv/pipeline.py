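"""End-to-end orchestration of the MR divergence analysis.

The full flow, per outcome dataset: harmonize the instruments, screen for
directional pleiotropy (MR-Egger intercept) and outlier pleiotropy
(MR-PRESSO global + outlier tests), exclude flagged variants, and run the
four causal estimators (IVW, weighted median, MR-Egger, PRESSO-corrected).
A secondary analysis repeats the estimators on the variants shared by
every outcome dataset minus the union of all flagged pleiotropic
variants, and each configured GWAS-vs-GWAX comparison gets per-variant
Cochran's Q / I^2 heterogeneity plus a paired t-test of the Wald
estimator vectors.  The report is a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .estimators import ivw, mr_egger, wald_estimates, weighted_median
from .harmonize import HarmonizedPanel, harmonize_panel
from .heterogeneity import count_heterogeneous, heterogeneity_table, paired_t_test
from .presso import presso_outlier_test
from .summary_io import SummaryDataset, intersect_datasets, read_summary_table, select_instruments


@dataclass
class AnalysisConfig:
    p_threshold: float = 5e-8
    palindrome_policy: str = "eaf_infer"
    eaf_window: float = 0.08
    n_sim: int = 10_000
    n_boot: int = 10_000
    alpha: float = 0.05
    ivw_model: str = "auto"
    seed: int = 0
    compare: list[tuple[str, str]] = field(default_factory=list)


def _subseed(seed: int, *names) -> int:
    h = int(seed)
    for n in names:
        h = (h * 1_000_003 + zlib.crc32(str(n).encode())) % (2**31 - 1)
    return h


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _four_methods(panel: HarmonizedPanel, config: AnalysisConfig, label: str) -> dict:
    est = wald_estimates(panel)
    results = {
        "IVW": ivw(est, model=config.ivw_model),
        "weighted_median": weighted_median(
            est, n_boot=config.n_boot, seed=_subseed(config.seed, "median", label)
        ),
        "MR_Egger": mr_egger(panel),
    }
    pres = presso_outlier_test(
        panel,
        n_sim=config.n_sim,
        seed=_subseed(config.seed, "presso-estimate", label),
        alpha=config.alpha,
    )
    results["MR_PRESSO"] = pres.corrected_estimate
    return {k: v.as_dict() for k, v in results.items()}


def run_full_analysis(
    exposure: SummaryDataset | str | Path,
    outcomes: dict[str, SummaryDataset | str | Path],
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the whole analysis and return the machine-readable report."""
    config = config or AnalysisConfig()
    provenance: dict = {"version": __version__, "seed": config.seed, "inputs": {}}

    if not isinstance(exposure, SummaryDataset):
        path = Path(exposure)
        provenance["inputs"]["exposure"] = {"path": str(path), "sha256": _sha256(path)}
        exposure = read_summary_table(path, label="exposure", trait_type="exposure")
    loaded: dict[str, SummaryDataset] = {}
    for label, src in outcomes.items():
        if isinstance(src, SummaryDataset):
            loaded[label] = src
        else:
            path = Path(src)
            provenance["inputs"][label] = {"path": str(path), "sha256": _sha256(path)}
            loaded[label] = read_summary_table(path, label=label, trait_type="outcome")
    if not loaded:
        raise ValueError("at least one outcome dataset is required")

    instruments = select_instruments(exposure, config.p_threshold)
    report: dict = {
        "provenance": provenance,
        "n_instruments": len(instruments),
        "datasets": {},
        "shared": {},
        "comparisons": {},
    }

    panels: dict[str, HarmonizedPanel] = {}
    flagged_union: set[str] = set()
    for label, outcome in loaded.items():
        stage = f"harmonize[{label}]"
        try:
            panel = harmonize_panel(
                instruments,
                outcome,
                palindrome_policy=config.palindrome_policy,
                eaf_window=config.eaf_window,
            )
            panels[label] = panel
            screen_egger = mr_egger(panel)
            pres = presso_outlier_test(
                panel,
                n_sim=config.n_sim,
                seed=_subseed(config.seed, "presso-screen", label),
                alpha=config.alpha,
            )
            stage = f"estimate[{label}]"
            flagged = pres.outlier_rsids
            flagged_union.update(flagged)
            kept = panel.subset([r for r in panel.rsids if r not in flagged])
            report["datasets"][label] = {
                "n_harmonized": len(panel),
                "dropped": [list(d) for d in panel.dropped],
                "pleiotropy_screen": {
                    "egger_intercept": screen_egger.egger_intercept,
                    "egger_intercept_ci": list(screen_egger.egger_intercept_ci),
                    "egger_intercept_p": screen_egger.egger_intercept_p,
                    "presso_global_p": pres.global_p,
                    "presso_rss": pres.rss_observed,
                    "pleiotropic_variants": flagged,
                },
                "excluded": flagged,
                "estimates": _four_methods(kept, config, label),
            }
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # secondary analysis on the variants present everywhere, minus every
    # flagged pleiotropic variant from any dataset
    shared_rsids = set(panels[next(iter(panels))].rsids)
    for panel in panels.values():
        shared_rsids &= set(panel.rsids)
    shared_rsids -= flagged_union
    shared_sorted = sorted(shared_rsids)
    report["shared"]["rsids_excluded"] = sorted(flagged_union)
    report["shared"]["n_shared"] = len(shared_sorted)
    shared_panels = {}
    if len(shared_sorted) >= 4:
        for label, panel in panels.items():
            sub = panel.subset(shared_sorted)
            shared_panels[label] = sub
            report["shared"].setdefault("estimates", {})[label] = _four_methods(
                sub, config, f"shared-{label}"
            )

    for pair in config.compare:
        a, b = pair
        if a not in shared_panels or b not in shared_panels:
            raise RuntimeError(f"stage heterogeneity[{a}:{b}] failed: missing panel")
        records = heterogeneity_table(shared_panels[a], shared_panels[b], shared_sorted)
        wa = {e.rsid: e.theta for e in wald_estimates(shared_panels[a])}
        wb = {e.rsid: e.theta for e in wald_estimates(shared_panels[b])}
        tt = paired_t_test(
            [wa[r] for r in shared_sorted], [wb[r] for r in shared_sorted]
        )
        report["comparisons"][f"{a}:{b}"] = {
            "counts": count_heterogeneous(records),
            "paired_t": asdict(tt),
            "records": [asdict(r) for r in records],
        }
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    """Write report.json plus flat TSVs shaped like the usual MR tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    screen_rows, est_rows, shared_rows = [], [], []
    for label, d in report["datasets"].items():
        s = d["pleiotropy_screen"]
        screen_rows.append(
            {
                "dataset": label,
                "n_variants": d["n_harmonized"],
                "egger_intercept": s["egger_intercept"],
                "egger_ci_low": s["egger_intercept_ci"][0],
                "egger_ci_high": s["egger_intercept_ci"][1],
                "egger_p": s["egger_intercept_p"],
                "presso_global_p": s["presso_global_p"],
                "pleiotropic_variants": ",".join(s["pleiotropic_variants"]) or "none",
            }
        )
        for method, e in d["estimates"].items():
            est_rows.append(
                {
                    "dataset": label,
                    "method": method,
                    "or": e["or"],
                    "or_low": e["or_low"],
                    "or_high": e["or_high"],
                    "pvalue": e["pvalue"],
                    "n_variants": e["n_variants"],
                }
            )
    for label, methods in report["shared"].get("estimates", {}).items():
        for method, e in methods.items():
            shared_rows.append(
                {
                    "dataset": label,
                    "method": method,
                    "or": e["or"],
                    "or_low": e["or_low"],
                    "or_high": e["or_high"],
                    "pvalue": e["pvalue"],
                    "n_variants": e["n_variants"],
                }
            )
    pd.DataFrame(screen_rows).to_csv(outdir / "pleiotropy_screen.tsv", sep="\t", index=False)
    pd.DataFrame(est_rows).to_csv(outdir / "mr_estimates.tsv", sep="\t", index=False)
    if shared_rows:
        pd.DataFrame(shared_rows).to_csv(
            outdir / "mr_estimates_shared.tsv", sep="\t", index=False
        )
    for pair, comp in report["comparisons"].items():
        safe = pair.replace(":", "_vs_")
        pd.DataFrame(comp["records"]).to_csv(
            outdir / f"heterogeneity_{safe}.tsv", sep="\t", index=False
        )
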