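"""End-to-end orchestration: simulate → extract → fit → assemble → test.

``run_all`` drives the whole quantitation chain on a synthetic cohort and
writes a report directory mirroring the structure of a dose-response lesion
study: per-animal bilateral Patlak fits, the cohort table with asymmetry
ratios, paired-t and ANOVA/Dunnett tables per measure, and the three
pairwise regressions (K_i asymmetry, monoamine asymmetry, log rotations)
with and without control animals.

Every output table carries a provenance header (config hash, seed,
conventions); identical configs reproduce outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .patlak import DEFAULT_WINDOW_MIN, fit_patlak, patlak_transform
from .stats import (
    dunnett_test,
    linear_regression,
    log_rotations,
    one_way_anova,
    paired_t_test,
)
from .synthetic import (
    DEFAULT_BOLUS,
    REFERENCE_KINETICS,
    CohortConfig,
    LinkParams,
    simulate_cohort,
    simulate_input_function,
    simulate_tissue_tac,
    striatal_params_for_ki,
)
from .tac import F18_HALF_LIFE_MIN, DEFAULT_FRAMING, DoseInfo, build_framing, to_suv

__all__ = ["ConfigError", "ComputationError", "RunConfig", "assemble_cohort", "run_all"]

logger = logging.getLogger("fdopaquant")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class ComputationError(RuntimeError):
    """A pipeline stage failed during computation (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Validated, serialisable configuration of one pipeline run."""

    framing: str = DEFAULT_FRAMING
    window_min: tuple[float, float] = DEFAULT_WINDOW_MIN
    half_life_min: float = F18_HALF_LIFE_MIN
    suv: bool = True
    dose_mbq: float = 55.0
    weight_g: float = 440.0
    simulate_kinetics: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        try:
            build_framing(self.framing)
            self.cohort.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if not self.window_min[0] < self.window_min[1]:
            raise ConfigError("Patlak window start must precede end")
        if self.half_life_min <= 0:
            raise ConfigError("half-life must be positive")
        if self.dose_mbq <= 0 or self.weight_g <= 0:
            raise ConfigError("dose and body weight must be positive")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_min"] = list(self.window_min)
        d["cohort"]["control_doses"] = list(self.cohort.control_doses)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "cohort" in d:
                c = dict(d["cohort"])
                for key in ("group_sizes", "severity_mean", "severity_sd"):
                    if key in c:
                        c[key] = {int(k): v for k, v in c[key].items()}
                for key in ("da_link", "rot_link"):
                    if key in c and isinstance(c[key], dict):
                        c[key] = LinkParams(**c[key])
                if "control_doses" in c:
                    c["control_doses"] = tuple(int(x) for x in c["control_doses"])
                d["cohort"] = CohortConfig(**c)
            if "window_min" in d:
                d["window_min"] = tuple(float(x) for x in d["window_min"])
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad run config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config file: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def assemble_cohort(
    patlak_df: pd.DataFrame,
    monoamine_df: pd.DataFrame,
    rotation_df: pd.DataFrame,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Inner-join the three per-animal measures into one complete-case table.

    Animals missing any of the three measures are excluded (and logged) —
    the correlation stage uses complete cases only.  Derived columns:
    ``ki_rl_percent``, ``da_rl_percent`` (ipsilateral/contralateral, %) and
    ``log_rotations`` (log10(count + log_offset)).

    Raises on duplicate animal ids or an empty intersection.
    """
    tables = {"patlak": patlak_df, "monoamine": monoamine_df, "rotation": rotation_df}
    for name, df in tables.items():
        if "animal_id" not in df.columns:
            raise ValueError(f"{name} table lacks an animal_id column")
        dup = df.animal_id[df.animal_id.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate animal_id in {name} table: {sorted(set(dup))}")
    merged = patlak_df.merge(monoamine_df, on="animal_id", how="inner").merge(
        rotation_df, on="animal_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no animal has all three measures: empty complete-case table")
    all_ids = set().union(*(set(df.animal_id) for df in tables.values()))
    excluded = sorted(all_ids - set(merged.animal_id))
    if excluded:
        logger.info("complete-case exclusion of %d animal(s): %s", len(excluded), excluded)
    merged = merged.copy()
    merged["ki_rl_percent"] = 100.0 * merged.ki_ipsi / merged.ki_contra
    merged["da_rl_percent"] = 100.0 * merged.da_ipsi / merged.da_contra
    merged["log_rotations"] = log_rotations(merged.rotations.to_numpy(), offset=log_offset)
    return merged


# ---------------------------------------------------------------------------
# Statistical battery on an assembled cohort table
# ---------------------------------------------------------------------------

def _anova_battery(df: pd.DataFrame, variables: list[str], control_dose: int,
                   seed: int) -> pd.DataFrame:
    rows = []
    doses = sorted(df.dose_ug.unique())
    for var in variables:
        groups = {d: df.loc[df.dose_ug == d, var].to_numpy() for d in doses}
        if len(groups) < 2:
            logger.info("single dose group: skipping ANOVA for %s", var)
            continue
        an = one_way_anova(groups)
        row = {
            "variable": var,
            "F": an.statistic,
            "df_between": an.df[0],
            "df_within": an.df[1],
            "p_value": an.p_value,
        }
        if control_dose in groups and len(groups) > 1:
            treatments = {d: g for d, g in groups.items() if d != control_dose}
            dn = dunnett_test(groups[control_dose], treatments, seed=seed)
            for d, (t, p_adj, p_un) in dn.per_group.items():
                row[f"dunnett_t_{d}ug"] = t
                row[f"dunnett_p_{d}ug"] = p_adj
        rows.append(row)
    return pd.DataFrame(rows)


def _paired_battery(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var in ("ki", "da"):
        for dose in sorted(df.dose_ug.unique()):
            sub = df[df.dose_ug == dose]
            try:
                res = paired_t_test(sub[f"{var}_ipsi"].to_numpy(),
                                    sub[f"{var}_contra"].to_numpy())
            except ValueError as exc:
                logger.info("paired t skipped for %s at %d ug: %s", var, dose, exc)
                continue
            rows.append(
                {
                    "variable": var,
                    "dose_ug": dose,
                    "n": len(sub),
                    "t": res.statistic,
                    "df": res.df[0],
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


REGRESSION_PAIRS = [
    ("ki_rl_percent", "da_rl_percent"),
    ("ki_rl_percent", "log_rotations"),
    ("da_rl_percent", "log_rotations"),
]


def _regression_battery(df: pd.DataFrame, control_doses: tuple[int, ...]) -> pd.DataFrame:
    rows = []
    lesioned = df[~df.dose_ug.isin(control_doses)]
    for include_controls, sub in (("yes", df), ("no", lesioned)):
        for xcol, ycol in REGRESSION_PAIRS:
            if len(sub) < 3:
                continue
            reg = linear_regression(sub[xcol].to_numpy(), sub[ycol].to_numpy())
            rows.append(
                {
                    "x": xcol,
                    "y": ycol,
                    "controls_included": include_controls,
                    "n": reg.n,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "pearson_r": reg.pearson_r,
                    "p_value": reg.p_value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _fit_cohort_kinetics(config: RunConfig, records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dynamic TACs per animal and re-estimate K_i by Patlak.

    Returns (per-animal Patlak K_i table, long fit-diagnostics table).  The
    cerebellar reference is common to all animals; striatal trapping per side
    is solved from each animal's ground-truth influx.  With SUV enabled both
    TACs are normalised identically, exercising the scale invariance of the
    transform.
    """
    scheme = build_framing(config.framing)
    plasma = simulate_input_function(DEFAULT_BOLUS, scheme.mid_times_min)
    ref_tac = simulate_tissue_tac(plasma, REFERENCE_KINETICS, scheme, region="cerebellum")
    dose = DoseInfo(config.dose_mbq, config.weight_g)

    def maybe_suv(tac):
        if not config.suv:
            return tac
        suv = to_suv(tac, dose)
        return dataclasses.replace(tac, values=suv.values)

    ref_used = maybe_suv(ref_tac)
    ki_rows, fit_rows = [], []
    for rec in records:
        row = {"animal_id": rec.animal_id, "dose_ug": rec.dose_ug}
        for side, ki_true in (("ipsi", rec.ki_ipsi), ("contra", rec.ki_contra)):
            params = striatal_params_for_ki(ki_true)
            tac = simulate_tissue_tac(plasma, params, scheme, region=f"striatum_{side}")
            pts = patlak_transform(maybe_suv(tac), ref_used)
            fit = fit_patlak(pts, config.window_min)
            row[f"ki_{side}"] = fit.ki
            fit_rows.append(
                {
                    "animal_id": rec.animal_id,
                    "side": side,
                    "ki_per_min": fit.ki,
                    "v": fit.v,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                    "window_min": f"{fit.window_min[0]:g}-{fit.window_min[1]:g}",
                    "ki_true": ki_true,
                }
            )
        ki_rows.append(row)
    return pd.DataFrame(ki_rows), pd.DataFrame(fit_rows)


def run_all(config: RunConfig, out_dir) -> Path:
    """Run the full chain and write the report directory.

    Deterministic given ``config`` (including its seed).  On failure a
    ``FAILED`` marker naming the stage is left in the output directory and
    the error re-raised as :class:`ConfigError`/:class:`ComputationError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        config.validate()
    except ConfigError:
        (out / "FAILED").write_text("configuration error\n")
        raise
    logging.basicConfig(level=config.log_level)
    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "patlak_window_min": f"{config.window_min[0]:g}-{config.window_min[1]:g}",
        "quadrature": "trapezoid on frame mid-times, initial triangle from origin",
        "log_rotation_offset": 1.0,
        "suv": config.suv,
    }
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        records = simulate_cohort(cohort_cfg)
        logger.info("simulated %d animals in %d dose groups",
                    len(records), len(cohort_cfg.group_sizes))

        base = fio.cohort_to_frame(records)
        if config.simulate_kinetics:
            ki_df, fits_df = _fit_cohort_kinetics(config, records)
            fio.write_table(fits_df, out / "patlak_fits.tsv", meta)
            patlak_df = ki_df
        else:
            patlak_df = base[["animal_id", "dose_ug", "ki_ipsi", "ki_contra"]]
        monoamine_df = base[["animal_id", "da_ipsi", "da_contra"]]
        rotation_df = base[["animal_id", "rotations"]]

        table = assemble_cohort(patlak_df, monoamine_df, rotation_df)
        fio.write_table(table, out / "cohort.tsv", meta)

        control = min(cohort_cfg.group_sizes)
        fio.write_table(_paired_battery(table), out / "paired_t.tsv", meta)
        anova = _anova_battery(
            table,
            ["ki_ipsi", "ki_contra", "da_ipsi", "da_contra"],
            control_dose=control,
            seed=config.seed + 1,
        )
        fio.write_table(anova, out / "anova_dunnett.tsv", meta)
        regs = _regression_battery(table, cohort_cfg.control_doses)
        fio.write_table(regs, out / "regressions.tsv", meta)

        _write_summary(out / "summary.txt", meta, table, anova, regs)
    except ConfigError:
        (out / "FAILED").write_text("configuration error\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"computation error: {exc}\n")
        raise ComputationError(str(exc)) from exc
    return out


def _write_summary(path: Path, meta: dict, table: pd.DataFrame,
                   anova: pd.DataFrame, regs: pd.DataFrame) -> None:
    lines = ["FDOPA quantitation pipeline summary", "=" * 36]
    lines += [f"{k}: {v}" for k, v in meta.items()]
    lines.append("")
    lines.append(f"animals (complete case): {len(table)}")
    for dose, sub in table.groupby("dose_ug"):
        lines.append(
            f"  {dose:>3} ug  n={len(sub)}  Ki R/L {sub.ki_rl_percent.mean():6.1f}% "
            f"(SD {sub.ki_rl_percent.std(ddof=1):.1f})  "
            f"DA R/L {sub.da_rl_percent.mean():6.1f}%  "
            f"rotations median {sub.rotations.median():.0f}"
        )
    lines.append("")
    if not anova.empty:
        lines.append("one-way ANOVA across dose groups:")
        for row in anova.itertuples(index=False):
            lines.append(
                f"  {row.variable}: F({row.df_between:.0f},{row.df_within:.0f}) = "
                f"{row.F:.2f}, p = {row.p_value:.2e}"
            )
    lines.append("")
    lines.append("pairwise regressions (complete case):")
    for row in regs.itertuples(index=False):
        lines.append(
            f"  {row.y} ~ {row.x} (controls {row.controls_included}): "
            f"slope {row.slope:.4g}, r = {row.pearson_r:.3f}, p = {row.p_value:.2e}, "
            f"n = {row.n}"
        )
    path.write_text("\n".join(lines) + "\n")
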