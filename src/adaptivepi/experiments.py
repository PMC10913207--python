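"""Experiment orchestration: configs, manifests, and the reproduction driver.

Every experiment writes plain-text outputs (CSV/JSON) into an output
directory and returns a manifest listing each file with a SHA-256 content
hash, plus the seeds and solver tolerances used — rerunning with the same
config and seed reproduces the files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .equilibria import equilibria_table, equilibrium_points
from .invariance import paired_output_test, Protocol, Verdict
from .models import AdaptivePIParams
from .reference import BASELINE_PARAMS, R0, D0, REFERENCE_SCENARIOS
from .signals import make_step_schedule
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    integrate,
    phase_portrait,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "compare_reference_values",
    "reproduce_reference",
]

EXPERIMENT_TYPES = ("equilibria", "phase_portrait", "step_response", "invariance")


@dataclass
class ExperimentConfig:
    """Validated description of one experiment run."""

    experiment: str
    params: AdaptivePIParams = field(default_factory=lambda: BASELINE_PARAMS)
    r: float = R0
    d: float = D0
    seed: int = 0
    out_dir: str = "out"
    # experiment-specific knobs (validated per type)
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        errors = []
        if self.experiment not in EXPERIMENT_TYPES:
            errors.append(f"experiment: must be one of {EXPERIMENT_TYPES}")
        if not isinstance(self.params, AdaptivePIParams):
            errors.append("params: expected an AdaptivePIParams instance")
        if not (isinstance(self.r, (int, float)) and self.r > 0):
            errors.append("r: must be a positive number")
        if not (isinstance(self.d, (int, float)) and self.d > 0):
            errors.append("d: must be a positive number")
        if not isinstance(self.seed, (int, np.integer)):
            errors.append("seed: must be an integer")
        if self.experiment == "invariance":
            missing = {"parameter_name", "p1", "p2"} - set(self.options)
            if missing:
                errors.append(f"options: invariance requires keys {sorted(missing)}")
        if errors:
            raise ValueError("invalid experiment config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping")
        param_keys = {"b", "s", "l", "c"}
        params = BASELINE_PARAMS.replace(**{k: raw.pop(k) for k in param_keys & set(raw)})
        known = {"experiment", "r", "d", "seed", "out_dir", "options"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(params=params, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(out_dir: Path, files, extra: dict) -> dict:
    manifest = {
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
        "solver": {"rtol": DEFAULT_RTOL, "atol": DEFAULT_ATOL},
    }
    manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_portrait(pp, out_dir: Path, stem: str) -> list:
    files = []
    field_path = out_dir / f"{stem}_field.csv"
    pp.field_frame().to_csv(field_path, index=False, float_format="%.10g")
    files.append(field_path)
    terminal = []
    for k, traj in enumerate(pp.trajectories):
        if traj is None:
            continue
        terminal.append(
            {
                "trajectory": k,
                "y0": traj.states[0, 0],
                "z0": traj.states[0, 1],
                "y_end": traj.states[-1, 0],
                "z_end": traj.states[-1, 1],
            }
        )
    import pandas as pd

    term_path = out_dir / f"{stem}_terminal_states.csv"
    pd.DataFrame(terminal).to_csv(term_path, index=False, float_format="%.10g")
    files.append(term_path)
    return files


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one configured experiment; returns its manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = dict(config.options)
    files = []
    extra = {"seed": int(config.seed), "experiment": config.experiment,
             "params": {k: float(v) for k, v in asdict(config.params).items()}}

    if config.experiment == "equilibria":
        table = equilibria_table(config.params, config.r, config.d)
        path = out_dir / "equilibria.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        files.append(path)
    elif config.experiment == "phase_portrait":
        pp = phase_portrait(
            config.params,
            config.r,
            config.d,
            grid_n=opts.get("grid_n", 15),
            horizon=opts.get("horizon", 60.0),
        )
        files += _write_portrait(pp, out_dir, "phase_portrait")
    elif config.experiment == "step_response":
        r_sig, d_sig = make_step_schedule(seed=config.seed)
        traj = integrate(
            "adaptive_pi",
            config.params,
            opts.get("x0", (8.0, 2.0)),
            r=r_sig,
            d=d_sig,
            t_span=(0.0, opts.get("t_end", 400.0)),
        )
        path = out_dir / "step_response.csv"
        traj.to_csv(path)
        files.append(path)
    elif config.experiment == "invariance":
        report = paired_output_test(
            opts["parameter_name"],
            opts["p1"],
            opts["p2"],
            protocol=opts.get("protocol", Protocol.STRICT),
            shared_seed=config.seed,
            base_params=config.params,
            t_end=opts.get("t_end", 400.0),
        )
        json_path = out_dir / "invariance_report.json"
        json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        csv_path = out_dir / "output_difference.csv"
        report.diff_frame().to_csv(csv_path, index=False, float_format="%.10g")
        files += [json_path, csv_path]
        extra["verdict"] = report.verdict.value

    return _manifest(out_dir, files, extra)


def compare_reference_values(scenarios=None, ndigits: int = 3) -> list:
    """Recompute equilibria/eigenvalues and compare to the reference table.

    Returns one record per scenario and quantity with the computed value,
    the reference value, and a match flag at ``ndigits`` rounding.
    """
    rows = []
    for scen in scenarios if scenarios is not None else REFERENCE_SCENARIOS:
        params = BASELINE_PARAMS.replace(**scen["overrides"])
        e1, e2 = equilibrium_points(params, R0, D0)
        computed = {
            "E1_y": e1.y,
            "E2_y": e2.y,
            "E2_z": e2.z,
            "lambda_E1_1": e1.eigenvalues[0].real,
            "lambda_E1_2": e1.eigenvalues[1].real,
            "lambda_E2_re": e2.eigenvalues[0].real,
            "lambda_E2_im": e2.eigenvalues[0].imag,
        }
        expected = {
            "E1_y": scen["E1_y"],
            "E2_y": scen["E2_y"],
            "E2_z": scen["E2_z"],
            "lambda_E1_1": scen["lambda_E1"][0],
            "lambda_E1_2": scen["lambda_E1"][1],
            "lambda_E2_re": scen["lambda_E2"][0],
            "lambda_E2_im": scen["lambda_E2"][1],
        }
        for key, value in computed.items():
            # the reference agrees to its printed precision; one unit in the
            # last printed digit absorbs round-versus-truncate ambiguity
            tol = 10.0 ** (-ndigits)
            rows.append(
                {
                    "scenario": scen["name"],
                    "quantity": key,
                    "computed": round(value, ndigits),
                    "reference": expected[key],
                    "match": abs(value - expected[key]) < tol,
                }
            )
    return rows


def reproduce_reference(
    out_dir,
    seed: int = 0,
    grid_n: int = 15,
    horizon: float = 60.0,
    t_end: float = 400.0,
) -> dict:
    """Recompute the full canonical analysis into ``out_dir``.

    Emits the reference-value comparison table, the four phase portraits
    (baseline and the s/b/c variants) and the three paired-response
    invariance experiments, then a manifest.  Any reference-value mismatch
    is recorded in the manifest with ``ok = False``.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []

    rows = compare_reference_values()
    cmp_path = out_dir / "reference_comparison.csv"
    pd.DataFrame(rows).to_csv(cmp_path, index=False, float_format="%.10g")
    files.append(cmp_path)
    all_match = all(r["match"] for r in rows)

    for scen in REFERENCE_SCENARIOS:
        params = BASELINE_PARAMS.replace(**scen["overrides"])
        pp = phase_portrait(params, R0, D0, grid_n=grid_n, horizon=horizon)
        files += _write_portrait(pp, out_dir, f"portrait_{scen['name']}")

    invariance_specs = [
        ("s", 0.25, 1.5),
        ("b", 0.3, 0.6),
        ("c", 2.0, 4.0),
    ]
    verdicts = {}
    for name, p1, p2 in invariance_specs:
        report = paired_output_test(
            name, p1, p2, protocol=Protocol.STRICT, shared_seed=seed, t_end=t_end
        )
        verdicts[name] = report.verdict.value
        json_path = out_dir / f"invariance_{name}.json"
        json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        csv_path = out_dir / f"invariance_{name}_diff.csv"
        report.diff_frame().to_csv(csv_path, index=False, float_format="%.10g")
        files += [json_path, csv_path]

    manifest = _manifest(
        out_dir,
        files,
        {
            "seed": int(seed),
            "reference_values_matched": all_match,
            "invariance_verdicts": verdicts,
            "ok": bool(
                all_match
                and verdicts.get("s") == Verdict.INVARIANT.value
                and verdicts.get("b") == Verdict.NOT_INVARIANT.value
                and verdicts.get("c") == Verdict.NOT_INVARIANT.value
            ),
        },
    )
    return manifest
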