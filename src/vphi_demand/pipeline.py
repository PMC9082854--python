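"""End-to-end orchestration: config, runs, threshold sweeps, report files.

A run executes read/generate -> currency conversion -> truncation ->
restriction columns -> two-step selection estimator -> instrumented probit
-> AMEs and elasticities -> bootstrap -> heterogeneity, and writes a report
directory of CSVs plus a JSON manifest from which every number is
replayable. All randomness (synthetic generation, bootstrap resampling)
derives from the single config seed by stream splitting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import survey_data as sd
from . import synthetic_survey as ss
from .elasticity import (
    ElasticityResult,
    bootstrap_inference,
    estimate_elasticities,
    estimate_sample,
    heterogeneity_analysis,
    heterogeneity_stats_fn,
    test_group_equality,
)
from .exceptions import ConfigurationError, VPHIError
from .survey_data import derive_vphi_indicator, descriptive_table, restrict_sample

logger = logging.getLogger("vphi_demand")

DEFAULT_RESTRICTIONS = ("all", "non_informal", "middle_income_up")


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    input_mode: str = "synthetic"  # "csv" | "synthetic"
    input_path: str | None = None
    column_map: Mapping[str, str] | None = None
    params: ss.StructuralParams | None = None
    n_synthetic: int = 50_000
    cop_per_usd: float | None = None  # set when amounts arrive in COP
    threshold_usd: float = 30.0
    restrictions: Sequence[str] = DEFAULT_RESTRICTIONS
    bootstrap: bool = True
    bootstrap_B: int = 200
    heterogeneity_groups: Sequence[str] = ("head_age_group", "member_over_65", "child_under_5")
    heterogeneity_bootstrap: bool = False
    sweep_thresholds: Sequence[float] | None = None
    seed: int = 0
    output_dir: str = "vphi_report"

    def validate(self) -> None:
        if self.input_mode not in ("csv", "synthetic"):
            raise ConfigurationError(f"input_mode must be csv|synthetic, got {self.input_mode!r}")
        if self.input_mode == "csv" and not self.input_path:
            raise ConfigurationError("input_mode=csv requires input_path")
        if self.threshold_usd < 0:
            raise ConfigurationError("threshold_usd must be >= 0")
        if self.bootstrap and self.bootstrap_B < 50:
            raise ConfigurationError("bootstrap_B must be >= 50 when inference is requested")
        for r in self.restrictions:
            if r not in sd.RESTRICTIONS:
                raise ConfigurationError(f"unknown restriction {r!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "params" in d and d["params"] is not None:
            p = d["params"]
            for key in ("contamination_range", "income_lognormal"):
                if key in p:
                    p[key] = tuple(p[key])
            d["params"] = ss.StructuralParams(**p)
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["params"] is not None:
            d["params"]["contamination_range"] = list(d["params"]["contamination_range"])
            d["params"]["income_lognormal"] = list(d["params"]["income_lognormal"])
        d["restrictions"] = list(d["restrictions"])
        d["heterogeneity_groups"] = list(d["heterogeneity_groups"])
        if d["sweep_thresholds"] is not None:
            d["sweep_thresholds"] = [float(t) for t in d["sweep_thresholds"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclasses.dataclass
class RunReport:
    descriptives: pd.DataFrame
    estimates: pd.DataFrame
    coefficients: pd.DataFrame
    results: dict[str, ElasticityResult]
    heterogeneity: dict[str, pd.DataFrame]
    equality_tests: dict[str, pd.DataFrame]
    sweep: pd.DataFrame | None
    histogram: pd.DataFrame
    manifest: dict


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2^31) from the single run seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _load_records(config: PipelineConfig, gen_seed: int) -> pd.DataFrame:
    if config.input_mode == "csv":
        records = sd.read_survey(config.input_path, config.column_map)
    else:
        params = config.params or ss.StructuralParams()
        records = ss.generate(params, config.n_synthetic, seed=gen_seed).records
    if config.cop_per_usd:
        records = records.copy()
        for col in ("premium_expenditure", "household_income"):
            records[col] = sd.convert_currency(records[col].to_numpy(), config.cop_per_usd)
    return records


def _premium_histogram(records: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    pos = records.loc[records["premium_expenditure"] > 0, "premium_expenditure"].to_numpy()
    if pos.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    top = float(np.quantile(pos, 0.99))
    edges = np.arange(0.0, max(top, bin_width) + bin_width, bin_width)
    counts, edges = np.histogram(pos, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def _stack_coefficients(restriction: str, chain) -> pd.DataFrame:
    """Long-form stage coefficients. The per-coefficient SEs are the naive
    single-stage ones (NaN where no covariance is kept); cross-stage
    uncertainty for the headline quantities comes from the bootstrap."""
    frames = []
    for stage, names, values, vcov in (
        ("reduced_probit", chain.reduced.names, chain.reduced.coefficients,
         chain.reduced.vcov),
        ("price_equation", chain.price.names, chain.price.delta_hat, None),
        ("structural_probit", chain.structural.names, chain.structural.beta_hat,
         chain.structural.vcov_naive),
    ):
        se = np.sqrt(np.diag(vcov)) if vcov is not None else np.full(len(names), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "restriction": restriction,
                    "stage": stage,
                    "coefficient": names,
                    "estimate": values,
                    "se_naive": se,
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "restriction": [restriction],
                "stage": ["price_equation"],
                "coefficient": ["mills_lambda"],
                "estimate": [chain.price.lambda_coef],
                "se_naive": [np.nan],
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and write the report directory."""
    config.validate()
    seeds = _spawn_seeds(config.seed, 2 + len(config.restrictions) + len(config.heterogeneity_groups))
    gen_seed = seeds[0]
    os.makedirs(config.output_dir, exist_ok=True)
    written: list[str] = []

    def _write(name: str, frame: pd.DataFrame, index=False) -> None:
        path = os.path.join(config.output_dir, name)
        frame.to_csv(path, index=index, float_format="%.10g")
        written.append(path)

    stage = "load"
    try:
        records = _load_records(config, gen_seed)
        n_read = len(records)
        logger.info("stage=load rows_read=%d", n_read)

        stage = "descriptives"
        desc = descriptive_table(records, config.threshold_usd)

        stage = "truncation"
        base = derive_vphi_indicator(records, config.threshold_usd)
        n_dropped_trunc = n_read - base.n
        logger.info(
            "stage=truncation threshold=%.2f kept=%d dropped=%d purchasers=%d",
            config.threshold_usd, base.n, n_dropped_trunc, base.n_purchasers,
        )

        results: dict[str, ElasticityResult] = {}
        coef_frames = []
        restriction_meta = {}
        for i, restriction in enumerate(config.restrictions):
            stage = f"estimation[{restriction}]"
            sub = restrict_sample(base, restriction)
            logger.info(
                "stage=restriction name=%s kept=%d dropped=%d purchasers=%d",
                restriction, sub.n, base.n - sub.n, sub.n_purchasers,
            )
            chain = estimate_sample(sub)
            coef_frames.append(_stack_coefficients(restriction, chain))
            if config.bootstrap:
                res = estimate_elasticities(
                    sub, B=config.bootstrap_B, seed=seeds[1 + i]
                )
            else:
                st = chain.stats
                res = ElasticityResult(
                    ame_price=st["ame_price"],
                    ame_income=st["ame_income"],
                    participation_share=st["participation_share"],
                    elasticity_price=st["elasticity_price"],
                    elasticity_income=st["elasticity_income"],
                    se={},
                    p_value={},
                    n=int(st["n"]),
                    n_purchasers=int(st["n_purchasers"]),
                )
            results[restriction] = res
            restriction_meta[restriction] = {
                "n": res.n,
                "n_purchasers": res.n_purchasers,
                "dropped_by_restriction": int(base.n - res.n),
            }

        stage = "heterogeneity"
        # run on the truncated, non-informal sample, with its own chain
        het_tables: dict[str, pd.DataFrame] = {}
        eq_tables: dict[str, pd.DataFrame] = {}
        if config.heterogeneity_groups:
            het_sample = restrict_sample(base, "non_informal")
            het_chain = estimate_sample(het_sample)
            for j, gvar in enumerate(config.heterogeneity_groups):
                het_tables[gvar] = heterogeneity_analysis(
                    het_sample, het_chain.lnp_hat, gvar
                )
                if config.heterogeneity_bootstrap:
                    boot = bootstrap_inference(
                        heterogeneity_stats_fn(gvar),
                        het_sample,
                        B=config.bootstrap_B,
                        seed=seeds[1 + len(config.restrictions) + j],
                    )
                    het_tables[gvar]["se_ame_price"] = [
                        boot.se.get(f"ame_price[{g}]", np.nan)
                        for g in het_tables[gvar]["group"]
                    ]
                    het_tables[gvar]["se_ame_income"] = [
                        boot.se.get(f"ame_income[{g}]", np.nan)
                        for g in het_tables[gvar]["group"]
                    ]
                    eq_tables[gvar] = test_group_equality(het_tables[gvar], boot)

        stage = "sweep"
        sweep = None
        if config.sweep_thresholds:
            sweep = threshold_sweep(records, list(config.sweep_thresholds))

        stage = "report"
        est_rows = {}
        for key in (
            "ame_price", "ame_income", "participation_share",
            "elasticity_price", "elasticity_income",
        ):
            est_rows[key] = {r: getattr(results[r], key) for r in results}
            est_rows[f"se_{key}"] = {r: results[r].se.get(key, np.nan) for r in results}
            est_rows[f"p_{key}"] = {r: results[r].p_value.get(key, np.nan) for r in results}
        est_rows["n"] = {r: results[r].n for r in results}
        est_rows["n_purchasers"] = {r: results[r].n_purchasers for r in results}
        estimates = pd.DataFrame(est_rows).T
        estimates.index.name = "statistic"

        coefficients = pd.concat(coef_frames, ignore_index=True)
        histogram = _premium_histogram(records)
        manifest = {
            "package_version": __version__,
            "seed": int(config.seed),
            "derived_seeds": seeds,
            "input_mode": config.input_mode,
            "input_path": config.input_path,
            "threshold_usd": float(config.threshold_usd),
            "cop_per_usd": config.cop_per_usd,
            "restrictions": list(config.restrictions),
            "bootstrap_B": int(config.bootstrap_B) if config.bootstrap else 0,
            "rows_read": int(n_read),
            "rows_dropped_truncation": int(n_dropped_trunc),
            "rows_after_truncation": int(base.n),
            "purchasers_after_truncation": int(base.n_purchasers),
            "per_restriction": restriction_meta,
            "versions": _library_versions(),
        }

        _write("descriptives.csv", desc, index=True)
        _write("estimates.csv", estimates, index=True)
        _write("coefficients.csv", coefficients)
        for gvar, tab in het_tables.items():
            _write(f"heterogeneity_{gvar}.csv", tab)
        for gvar, tab in eq_tables.items():
            _write(f"equality_{gvar}.csv", tab)
        if sweep is not None:
            _write("sweep.csv", sweep)
        _write("premium_histogram.csv", histogram)
        mpath = os.path.join(config.output_dir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(mpath)
        logger.info("stage=report files=%d dir=%s", len(written), config.output_dir)
    except VPHIError as exc:
        for path in written:  # no partial reports
            if os.path.exists(path):
                os.remove(path)
        raise type(exc)(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return RunReport(
        descriptives=desc,
        estimates=estimates,
        coefficients=coefficients,
        results=results,
        heterogeneity=het_tables,
        equality_tests=eq_tables,
        sweep=sweep,
        histogram=histogram,
        manifest=manifest,
    )


def threshold_sweep(
    records: pd.DataFrame,
    thresholds: Sequence[float],
    restriction: str = "all",
    min_purchasers: int = 30,
) -> pd.DataFrame:
    """Re-estimate the chain at each truncation threshold (no bootstrap).

    A threshold leaving fewer than ``min_purchasers`` purchasers is flagged
    ``insufficient`` rather than estimated.
    """
    if len(thresholds) < 2:
        raise ConfigurationError("threshold_sweep needs at least 2 thresholds")
    rows = []
    for t in thresholds:
        sample = restrict_sample(derive_vphi_indicator(records, float(t)), restriction)
        row = {
            "threshold": float(t),
            "n": sample.n,
            "n_purchasers": sample.n_purchasers,
            "status": "ok",
            "ame_price": np.nan,
            "elasticity_price": np.nan,
            "beta1": np.nan,
        }
        if sample.n_purchasers < min_purchasers:
            row["status"] = "insufficient"
        else:
            try:
                st = estimate_sample(sample).stats
                row.update(
                    ame_price=st["ame_price"],
                    elasticity_price=st["elasticity_price"],
                    beta1=st["beta1"],
                )
            except (VPHIError, np.linalg.LinAlgError) as exc:
                row["status"] = f"failed: {type(exc).__name__}"
        rows.append(row)
    return pd.DataFrame(rows)


def _library_versions() -> dict[str, str]:
    import pandas
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
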