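"""Delimited-text I/O and run configuration.

All tables are CSV with a header row.  CoP traces carry their sampling rate
in a ``# rate_hz=...`` comment line above the header.  Unknown extra columns
are preserved on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDesign, CoPParams
from .errors import InvalidParameterError, SchemaError
from .uncertainty import REQUIRED_TRIAL_COLUMNS
from .vtc import TAU_MAX_DEFAULT, BaseOfSupport, CoPTrace

_TRIAL_NUMERIC = ("visit", "block", "trial", "shift", "deviation")


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table is missing column(s): {', '.join(missing)}")
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in _TRIAL_NUMERIC:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise SchemaError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = vals
    if not np.isfinite(df[["shift", "deviation"]].to_numpy()).all():
        raise SchemaError(f"{path}: shift/deviation must be finite")
    return df


def write_cop(trace: CoPTrace, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame({"t": trace.t, "ap": trace.ap, "ml": trace.ml})
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={trace.rate}\n")
        frame.to_csv(fh, index=False)


def read_cop(path: str | Path) -> CoPTrace:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# rate_hz="):
            raise SchemaError(f"{path}: expected a '# rate_hz=...' header line")
        try:
            rate = float(first.split("=", 1)[1])
        except ValueError as exc:
            raise SchemaError(f"{path}: unparseable sampling rate {first!r}") from exc
        df = pd.read_csv(fh)
    for col in ("t", "ap", "ml"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="raise")
    t = df["t"].to_numpy()
    dt = np.diff(t)
    if dt.size and np.any(np.abs(dt - dt[0]) > 1e-9):
        raise SchemaError(f"{path}: timestamps are not uniformly spaced")
    return CoPTrace(t=t, ap=df["ap"].to_numpy(), ml=df["ml"].to_numpy(), rate=rate)


@dataclass
class VtcOptions:
    cutoff_hz: float = 10.0
    tau_max_s: float = TAU_MAX_DEFAULT
    cap_policy: str = "include_capped"
    bos_a_ml_cm: float = 5.0
    bos_b_ap_cm: float = 12.0

    def boundary(self) -> BaseOfSupport:
        return BaseOfSupport(a_ml=self.bos_a_ml_cm, b_ap=self.bos_b_ap_cm)


@dataclass
class RunConfig:
    """Complete configuration of an end-to-end pipeline run.

    Round-trips losslessly through YAML; every field has a documented
    default (see ``docs/methods.md``).
    """

    design: CohortDesign = field(default_factory=CohortDesign)
    cop: CoPParams = field(default_factory=CoPParams)
    vtc: VtcOptions = field(default_factory=VtcOptions)
    per_block: bool = True
    make_figures: bool = True
    seed: int = 0

    def resolved(self) -> "RunConfig":
        """Copy with the top-level seed pushed into the generator design."""
        return dataclasses.replace(
            self, design=dataclasses.replace(self.design, seed=self.seed)
        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        d = {
            "design": enc(self.design),
            "cop": enc(self.cop),
            "vtc": enc(self.vtc),
            "per_block": self.per_block,
            "make_figures": self.make_figures,
            "seed": self.seed,
        }
        # the boundary dataclass nests inside cop; drop unset polygon vertices
        if d["cop"]["boundary"].get("vertices") is None:
            d["cop"]["boundary"].pop("vertices")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design = CohortDesign(**d.get("design", {}))
        cop_d = dict(d.get("cop", {}))
        if "boundary" in cop_d:
            b = dict(cop_d["boundary"])
            if "center" in b:
                b["center"] = tuple(b["center"])
            if b.get("vertices") is not None:
                b["vertices"] = np.asarray(b["vertices"], dtype=float)
            cop_d["boundary"] = BaseOfSupport(**b)
        if "sway_scale" in cop_d:
            cop_d["sway_scale"] = tuple(cop_d["sway_scale"])
        cop = CoPParams(**cop_d)
        vtc = VtcOptions(**d.get("vtc", {}))
        return cls(
            design=design,
            cop=cop,
            vtc=vtc,
            per_block=bool(d.get("per_block", True)),
            make_figures=bool(d.get("make_figures", True)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise InvalidParameterError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(d)


def write_report(results: dict, out_dir: str | Path) -> None:
    """Write the analysis bundle: delimited tables plus a plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("anova", "tukey_cells", "balance_anova", "balance_tukey"):
        if name in results:
            results[name].to_csv(out / f"{name}.csv", index=False)
    if "contrasts" in results:
        pd.DataFrame([dataclasses.asdict(c) for c in results["contrasts"]]).to_csv(
            out / "contrasts.csv", index=False
        )
    lines = ["stepsense analysis summary", "=" * 26, ""]
    if "anova" in results:
        lines.append("Group x visit repeated-measures ANOVA on RMSE (cm):")
        lines.append(results["anova"].to_string(index=False))
        lines.append("")
    if "contrasts" in results:
        lines.append("Planned contrasts (cm, unadjusted):")
        for c in results["contrasts"]:
            ci = (
                f" 95% CI [{c.ci_low:.3f}, {c.ci_high:.3f}], p={c.p_value:.3f}"
                if c.se is not None
                else ""
            )
            lines.append(f"  {c.label}: {c.estimate:.3f}{ci}")
        lines.append("")
    if "balance_anova" in results:
        lines.append("TENS x condition repeated-measures ANOVA on mean VTC (s):")
        lines.append(results["balance_anova"].to_string(index=False))
        lines.append("")
    if "warnings" in results and results["warnings"]:
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in results["warnings"])
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
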