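"""End-to-end orchestration: simulate/load -> align -> detrend -> PDE ->
fit/select -> classify -> goodness-of-fit -> compare, with a manifest.

A single root seed fans out into per-stage sub-seeds (``SeedSequence``) so
any stage can be re-run in isolation and two runs with the same seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import build_comparison, class_summaries, group_by_mode
from .detrend import DetrendConfig, detrend_table
from .errors import ConfigurationError
from .mixture import classify, em_fit, goodness_of_fit, select_k
from .pde import pde_estimate
from .synthetic import GapSpec, MixtureSpec, generate
from .timetable import AlignmentPolicy, TimeTable, align, read_table, write_table

logger = logging.getLogger(__name__)

RESIDUAL_SUFFIX = "~"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see ``RunConfig.from_yaml``)."""

    output_dir: str = "streammodes_out"
    seed: int = 0
    input_path: str | None = None
    simulate: dict | None = None
    nitrate_column: str = "NO3"
    align: dict = field(default_factory=dict)
    do_align: bool = False
    detrend: dict = field(default_factory=dict)
    pde: dict = field(default_factory=dict)
    mixture: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of 'input' and 'simulate' must be configured")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(
            output_dir=raw.get("output_dir", "streammodes_out"),
            seed=int(raw.get("seed", 0)),
            input_path=raw.get("input"),
            simulate=raw.get("simulate"),
            nitrate_column=raw.get("nitrate_column", "NO3"),
            align=raw.get("align") or {},
            do_align="align" in raw,
            detrend=raw.get("detrend") or {},
            pde=raw.get("pde") or {},
            mixture=raw.get("mixture") or {},
            compare=raw.get("compare") or {},
        )

    def echo(self) -> dict:
        return {
            "output_dir": self.output_dir, "seed": self.seed,
            "input": self.input_path, "simulate": self.simulate,
            "nitrate_column": self.nitrate_column,
            "align": self.align if self.do_align else None,
            "detrend": self.detrend, "pde": self.pde,
            "mixture": self.mixture, "compare": self.compare,
        }


def _sub_seeds(root: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds derived from the root seed."""
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _write_curve(curve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pareto_radius={curve.pareto_radius!r} n={curve.n}\n")
        pd.DataFrame({"grid": curve.grid, "density": curve.density}).to_csv(fh, index=False)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed)
    artifacts: list[str] = []
    stage = "setup"
    try:
        # ------------------------------------------------------------ input
        stage = "input"
        if config.simulate is not None:
            sim = dict(config.simulate)
            mixture = MixtureSpec(**sim.pop("mixture", {}))
            gaps = GapSpec(**sim.pop("gaps", {}))
            table = generate(mixture=mixture, gaps=gaps, seed=seeds[0],
                             nitrate_column=config.nitrate_column, **sim)
        else:
            table = read_table(config.input_path)
        if config.nitrate_column not in table.columns:
            raise ConfigurationError(
                f"nitrate column {config.nitrate_column!r} not found in input")

        if config.do_align:
            stage = "align"
            table = align(table, AlignmentPolicy(**config.align))

        # ---------------------------------------------------------- detrend
        stage = "detrend"
        zb = config.detrend.get("zero_baseline")
        if zb is None:  # the default roster, trimmed to the columns present
            zb = frozenset(("rain", "q13", "q18")) & set(table.columns)
        dconf = DetrendConfig(
            zero_baseline_variables=frozenset(zb),
            **{k: v for k, v in config.detrend.items() if k != "zero_baseline"})
        logger.info("detrend: cutoff=%s d, zero-baseline=%s",
                    dconf.cutoff_period, sorted(dconf.zero_baseline_variables))
        result = detrend_table(table, dconf)
        _write_suffixed(result.baseline, out / "baseline.csv")
        _write_suffixed(result.residual, out / "residuals.csv")
        artifacts += ["baseline.csv", "residuals.csv"]

        nitrate = result.residual.frame[config.nitrate_column].to_numpy(dtype=float)

        # -------------------------------------------------------------- PDE
        stage = "pde"
        pde_kwargs = dict(config.pde)
        pde_kwargs.setdefault("seed", seeds[1])
        curve = pde_estimate(nitrate, **pde_kwargs)
        logger.info("pde: radius=%.5g (quantile=%s)", curve.pareto_radius,
                    pde_kwargs.get("quantile", 0.18))
        _write_curve(curve, out / "pde_curve.csv")
        artifacts.append("pde_curve.csv")

        # -------------------------------------------------- mixture fitting
        stage = "fit"
        mconf = dict(config.mixture)
        k_min = int(mconf.pop("k_min", 1))
        k_max = int(mconf.pop("k_max", 10))
        criterion = mconf.pop("criterion", "both")
        init = mconf.pop("init", None)
        mconf.setdefault("seed", seeds[2])
        selection = select_k(nitrate, k_min, k_max, criterion=criterion, **mconf)
        fit = selection.best_fit
        if init is not None:
            # the user-defined start refines the chosen K
            fit = em_fit(nitrate, fit.K, init=init, **{
                k: v for k, v in mconf.items() if k in ("tol", "max_iter")})
        pd.DataFrame(selection.rows).to_csv(out / "model_selection.csv", index=False)
        with open(out / "model.json", "w") as fh:
            json.dump({**fit.to_dict(), "chosen_by": selection.criterion,
                       "aic_bic_agree": selection.agree}, fh, indent=2)
        artifacts += ["model_selection.csv", "model.json"]

        # ----------------------------------------------------- classify/GoF
        stage = "classify"
        assignment = classify(fit, nitrate)
        cls_frame = pd.DataFrame(
            {"residual": nitrate,
             **{f"posterior_{name}": assignment.posteriors[:, k]
                for k, name in enumerate(assignment.class_names)},
             "label": [assignment.class_names[l] if l >= 0 else ""
                       for l in assignment.labels]},
            index=table.timestamps)
        cls_frame.to_csv(out / "classification.csv",
                         date_format="%Y-%m-%dT%H:%M:%S")
        artifacts.append("classification.csv")

        stage = "gof"
        gof = goodness_of_fit(fit, nitrate)
        with open(out / "gof.json", "w") as fh:
            json.dump({"chi2_stat": gof.chi2_stat, "chi2_df": gof.chi2_df,
                       "chi2_p": gof.chi2_p, "ks_stat": gof.ks_stat,
                       "ks_p": gof.ks_p, "warning": gof.warning,
                       "qq_pairs": gof.qq_pairs.tolist()}, fh, indent=2)
        artifacts.append("gof.json")

        # ----------------------------------------------------------- compare
        stage = "compare"
        cconf = dict(config.compare)
        alpha = float(cconf.pop("alpha", 0.01))
        scope = cconf.pop("scope", "global")
        covariates = [c for c in result.residual.columns if c != config.nitrate_column]
        groups = {v: group_by_mode(assignment, result, v) for v in covariates}
        comparison = build_comparison(groups, alpha=alpha, correction_scope=scope)
        logger.info("compare: alpha=%s scope=%s m=%d", alpha, scope, comparison.correction_m)
        frame = comparison.to_frame()
        frame.index = [v + RESIDUAL_SUFFIX for v in frame.index]
        frame.to_csv(out / "comparison.tsv", sep="\t")
        artifacts.append("comparison.tsv")

        rows = []
        for var in covariates:
            summary = class_summaries(groups[var], with_pde=False)
            for cls, st in summary.stats.items():
                rows.append({"variable": var + RESIDUAL_SUFFIX, "class": cls, **st})
        pd.DataFrame(rows).to_csv(out / "class_summaries.csv", index=False)
        artifacts.append("class_summaries.csv")
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs in %s", stage, out)
        raise

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.echo(),
        "versions": _versions(),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_suffixed(table: TimeTable, path) -> None:
    """Write a residual/baseline table with '~' appended to data columns."""
    renamed = table.frame.rename(
        columns={c: c + RESIDUAL_SUFFIX for c in table.columns})
    write_table(TimeTable(renamed), path)


def _versions() -> dict:
    import scipy
    return {"streammodes": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
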