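"""End-to-end study orchestration from one config file.

For each configured exposure: significance screen → LD clumping → (per
outcome cohort) proxy lookup + harmonization → all MR estimators and
sensitivity analyses; then SNP-level fixed-effect meta-analysis across the
designated cohort pair followed by MR on the combined statistics; Bonferroni
adjustment across the exposure family within each cohort; and an analytic
power table.  Every configured exposure×outcome pair appears in the report
exactly once, either with results or with an explicit skip reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import gwas_io
from .gwas_io import LDMatrix, ProxyRecord, SummaryStatRecord
from .harmonize import HarmonizationAudit, HarmonizedInstrument, harmonize_set
from .instruments import InstrumentSet, build_instrument_set, mr_power
from .meta import meta_sumstats
from .mr import MRAnalysis, MRConfig, run_all_methods

logger = logging.getLogger("coagmr")

EXPOSURE_CATEGORIES = (
    "platelet adhesion", "intrinsic pathway", "extrinsic pathway",
    "common pathway", "fibrin clot dissociation",
)


@dataclass
class ExposureSpec:
    name: str
    sumstats: str
    n: int
    category: str = ""


@dataclass
class OutcomeSpec:
    name: str
    cohort: str
    sumstats: str
    n_case: int
    n_control: int
    subphenotype: bool = False

    @property
    def n(self) -> int:
        return self.n_case + self.n_control

    @property
    def case_ratio(self) -> float:
        return self.n_case / self.n_control


@dataclass
class Thresholds:
    p_select: float = 5e-7
    clump_r2: float = 0.1
    clump_kb: int = 10_000
    proxy_r2: float = 0.8
    alpha: float = 0.05
    eaf_tolerance: float = 0.08
    m_tests: int = 11


@dataclass
class StudyConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    ld: str | None = None
    proxies: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    meta_members: list[str] = field(default_factory=list)
    meta_name: str = "meta"
    #: Exposures carried into sub-phenotype outcomes; empty = all.
    subphenotype_exposures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.exposures]
        if len(names) != len(set(names)):
            raise ValueError(f"exposure names not unique: {names}")
        t = self.thresholds
        if not (0 < t.p_select < 1 and 0 <= t.clump_r2 <= 1
                and t.clump_kb > 0 and 0 < t.proxy_r2 < 1
                and 0 < t.alpha < 1 and 0 <= t.eaf_tolerance < 0.5
                and t.m_tests >= 1):
            raise ValueError(f"threshold out of domain: {t}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            exposures=[ExposureSpec(**e) for e in raw["exposures"]],
            outcomes=[OutcomeSpec(**o) for o in raw["outcomes"]],
            ld=raw.get("ld"), proxies=raw.get("proxies"),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            seed=int(raw.get("seed", 0)),
            meta_members=list(raw.get("meta_members", [])),
            meta_name=raw.get("meta_name", "meta"),
            subphenotype_exposures=list(raw.get("subphenotype_exposures", [])),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path


@dataclass
class PairResult:
    exposure: str
    outcome: str
    analysis: MRAnalysis | None = None
    audit: HarmonizationAudit | None = None
    harmonized: list[HarmonizedInstrument] = field(default_factory=list)
    skip_reason: str | None = None


@dataclass
class ReportBundle:
    pairs: dict[tuple[str, str], PairResult]
    instrument_sets: dict[str, InstrumentSet]
    power_rows: list[dict]
    metadata: dict


def _pair_seed(base_seed: int, i_exp: int, i_out: int) -> int:
    # Deterministic, collision-free per-pair seed below 2**31.
    return (base_seed * 1_000_003 + i_exp * 1_009 + i_out) % (2**31 - 1)


def run_pipeline(
    config: StudyConfig,
    exposure_records: dict[str, list[SummaryStatRecord]] | None = None,
    outcome_records: dict[str, list[SummaryStatRecord]] | None = None,
    ld: LDMatrix | None = None,
    proxies: list[ProxyRecord] | None = None,
) -> ReportBundle:
    """Run the whole study.  Inputs may be passed in-memory or read from the
    paths in ``config``; in-memory values win, which is how the simulator and
    the tests drive the pipeline without touching disk."""
    t = config.thresholds
    if exposure_records is None:
        exposure_records = {e.name: gwas_io.read_sumstats(e.sumstats, trait=e.name)[0]
                            for e in config.exposures}
    if outcome_records is None:
        outcome_records = {o.name: gwas_io.read_sumstats(o.sumstats, trait=o.name)[0]
                           for o in config.outcomes}
    if ld is None:
        if config.ld:
            ld = gwas_io.read_ld_matrix(config.ld)
        else:
            from .simulate import identity_ld
            all_ids = sorted({r.snp_id for recs in exposure_records.values()
                              for r in recs})
            ld = identity_ld(all_ids)
    if proxies is None:
        proxies = gwas_io.read_proxy_table(config.proxies) if config.proxies else []

    outcomes = list(config.outcomes)
    if len(config.meta_members) >= 2:
        members = [o for o in outcomes if o.name in config.meta_members]
        combined, _ = meta_sumstats(
            outcome_records[members[0].name], outcome_records[members[1].name],
            eaf_tolerance=t.eaf_tolerance)
        for extra in members[2:]:
            combined, _ = meta_sumstats(combined, outcome_records[extra.name],
                                        eaf_tolerance=t.eaf_tolerance)
        meta_outcome = OutcomeSpec(
            name=config.meta_name, cohort=config.meta_name, sumstats="",
            n_case=sum(m.n_case for m in members),
            n_control=sum(m.n_control for m in members))
        outcome_records[config.meta_name] = combined
        outcomes.append(meta_outcome)

    instrument_sets: dict[str, InstrumentSet] = {}
    for exp in config.exposures:
        instrument_sets[exp.name] = build_instrument_set(
            exp.name, exposure_records[exp.name], ld,
            p_threshold=t.p_select, r2_max=t.clump_r2,
            window_bp=t.clump_kb * 1000, n=exp.n)

    pairs: dict[tuple[str, str], PairResult] = {}
    power_rows: list[dict] = []
    for i_out, out in enumerate(outcomes):
        for i_exp, exp in enumerate(config.exposures):
            key = (exp.name, out.name)
            if (out.subphenotype and config.subphenotype_exposures
                    and exp.name not in config.subphenotype_exposures):
                pairs[key] = PairResult(exp.name, out.name,
                                        skip_reason="not_carried_to_subphenotype")
                continue
            iset = instrument_sets[exp.name]
            if iset.k == 0:
                pairs[key] = PairResult(exp.name, out.name,
                                        skip_reason="no_instruments")
                continue
            harmonized, audit = harmonize_set(
                iset, outcome_records[out.name], proxy_table=proxies,
                eaf_tolerance=t.eaf_tolerance, proxy_r2_min=t.proxy_r2)
            if not harmonized:
                pairs[key] = PairResult(exp.name, out.name, audit=audit,
                                        skip_reason="no_snps_after_harmonization")
                continue
            mr_config = MRConfig(
                alpha=t.alpha, m_tests=t.m_tests,
                seed=_pair_seed(config.seed, i_exp, i_out),
                n_exposure=exp.n, n_outcome=out.n)
            analysis = run_all_methods(harmonized, mr_config)
            pairs[key] = PairResult(exp.name, out.name, analysis=analysis,
                                    audit=audit, harmonized=harmonized)
            ivw = next(r for r in analysis.results if r.method == "ivw_fixed")
            power_rows.append({
                "exposure": exp.name, "outcome": out.name,
                "n_outcome": out.n, "r2": iset.r2_explained,
                "case_ratio": out.n_case / out.n_control,
                "beta_alt": ivw.beta,
                "power": mr_power(out.n, iset.r2_explained,
                                  out.n_case / out.n_control, ivw.beta,
                                  alpha=t.alpha).power,
            })

    metadata = {
        "seed": config.seed,
        "thresholds": asdict(t),
        "meta_scheme": "fixed_effect_stderr",
        "wm_estimator": "weighted_median_bootstrap_se",
        "egger_se_inflation": True,
        "steiger_r2": "z_based",
        "adjustment": "bonferroni",
    }
    return ReportBundle(pairs=pairs, instrument_sets=instrument_sets,
                        power_rows=power_rows, metadata=metadata)


def forest_data(bundle: ReportBundle, method: str = "ivw_fixed") -> list[dict]:
    """Per exposure×cohort rows of OR, 95% CI, p and a significance flag.

    Row order follows the configured exposure order within each cohort.
    Raises when the requested method was computed for no pair.
    """
    alpha = bundle.metadata["thresholds"]["alpha"]
    rows, methods_seen = [], set()
    for (exposure, outcome), pair in bundle.pairs.items():
        if pair.analysis is None:
            continue
        methods_seen.update(r.method for r in pair.analysis.results)
        match = [r for r in pair.analysis.results if r.method == method]
        if not match:
            continue
        r = match[0]
        rows.append({
            "exposure": exposure, "cohort": outcome, "nsnp": r.nsnp,
            "or": r.or_, "ci_low": r.or_ci_low, "ci_high": r.or_ci_high,
            "pval": r.pval, "pval_adjusted": r.pval_adjusted,
            "significant": r.pval < alpha,
        })
    if not rows:
        raise ValueError(
            f"method {method!r} absent from bundle; available: "
            f"{sorted(methods_seen)}")
    return rows


def results_rows(bundle: ReportBundle) -> dict[str, list[dict]]:
    """Flatten a bundle into per-cohort result-table rows for gwas_io."""
    tables: dict[str, list[dict]] = {}
    for (exposure, outcome), pair in sorted(bundle.pairs.items(),
                                            key=lambda kv: (kv[0][1], kv[0][0])):
        rows = tables.setdefault(outcome, [])
        if pair.analysis is None:
            rows.append({"exposure": exposure, "method": "skipped",
                         "nsnp": 0, "pval": None,
                         "steiger_direction": pair.skip_reason})
            continue
        s = pair.analysis.sensitivity
        for r in pair.analysis.results:
            rows.append({
                "exposure": exposure, "method": r.method, "nsnp": r.nsnp,
                "beta": r.beta, "se": r.se, "or": r.or_,
                "ci_low": r.or_ci_low, "ci_high": r.or_ci_high,
                "pval": r.pval, "pval_adjusted": r.pval_adjusted,
                "q": s.q_ivw, "q_pval": s.q_ivw_pval,
                "egger_intercept": s.egger_intercept,
                "intercept_pval": s.intercept_pval,
                "steiger_direction": (None if s.steiger_direction is None else
                                      ("exposure_to_outcome" if s.steiger_direction
                                       else "outcome_to_exposure")),
                "steiger_pval": s.steiger_pval,
            })
    return tables


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Serialize a bundle as a directory of TSVs plus run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = gwas_io.write_result_tables(results_rows(bundle), outdir)

    power_path = outdir / "power.tsv"
    cols = ["exposure", "outcome", "n_outcome", "r2", "case_ratio",
            "beta_alt", "power"]
    with open(power_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in bundle.power_rows:
            fh.write("\t".join(gwas_io._fmt(row[c]) for c in cols) + "\n")
    manifest.append(power_path)

    forest_path = outdir / "forest_ivw_fixed.tsv"
    rows = forest_data(bundle)
    fcols = ["exposure", "cohort", "nsnp", "or", "ci_low", "ci_high",
             "pval", "pval_adjusted", "significant"]
    with open(forest_path, "w") as fh:
        fh.write("\t".join(fcols) + "\n")
        for row in rows:
            fh.write("\t".join(gwas_io._fmt(row[c]) for c in fcols) + "\n")
    manifest.append(forest_path)

    meta_path = outdir / "run_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(bundle.metadata, fh, sort_keys=True)
    manifest.append(meta_path)
    return manifest
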