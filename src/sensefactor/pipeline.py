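"""End-to-end orchestration: structure evaluation, scoring, and correlates.

A pipeline run takes an ordinal response matrix (plus optional correlates),
a construct definition (item -> specific-factor map, from a packaged loading
table or a custom table), and produces a run directory containing:

* ``ega.json`` — community structure of the item network;
* ``bifactor.json`` — the fitted bifactor graded response model;
* ``indices.json`` / ``verdicts.json`` — bifactor indices and the
  interpretability / added-value decisions;
* EAP score tables, emitted only for interpretable targets: the general
  factor score when the general factor is strong, and one unidimensional
  subscale score per added-value specific factor;
* ``ida/`` — effect-size summaries per emitted score × correlate;
* ``manifest.json`` — seed, stage timings, and SHA-256 hashes of every
  artifact, so identical configurations are verifiably identical runs.

Any stage failure preserves completed artifacts and records a
machine-readable error in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grm import eap_scores, fit_bifactor_grm, fit_unidimensional_grm, marginal_reliability
from .ida import IdaModelSpec, IdaRefusal, effect_size_summary, evidence_tally, fit_ida_model
from .item_bank import CorrelateTable, OrdinalResponseMatrix
from .polychoric import polychoric_matrix
from .structure import bifactor_indices, ega, interpretability_rules
from .tables import load_loading_table

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    out_dir: str
    responses: str | None = None  # CSV path; or provide matrix directly
    correlates: str | None = None
    construct: str = "HYPER"  # packaged loading table key or path to a CSV
    seed: int = 0
    ida_draws: int = 500
    ida_chains: int = 4
    run_ida: bool = True
    grm_tol: float = 1e-5
    grm_max_cycles: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _load_structure(construct: str) -> pd.DataFrame:
    p = Path(construct)
    if p.suffix == ".csv" and p.exists():
        df = pd.read_csv(p, dtype={"item": str, "specific_factor": str})
        df["specific_factor"] = df["specific_factor"].fillna("")
        return df
    return load_loading_table(construct)


def run_pipeline(
    config: PipelineConfig,
    matrix: OrdinalResponseMatrix | None = None,
    correlates: CorrelateTable | None = None,
) -> Path:
    """Execute the structure -> score -> correlate pipeline.

    Data may be passed in memory or read from the configured CSV paths.
    Returns the run directory; inspect ``manifest.json`` there for status.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "construct": config.construct,
                      "stages": {}, "errors": [], "artifacts": {}}
    t_all = time.time()

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.time() - self.t0, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    manifest["errors"].append(
                        {"stage": name, "error": f"{exc_type.__name__}: {exc}"})
                return False
        return _Timer()

    try:
        with stage("load"):
            if matrix is None:
                if config.responses is None:
                    raise ValueError("no response matrix provided")
                matrix = OrdinalResponseMatrix.load(config.responses)
            if correlates is None and config.correlates:
                correlates = CorrelateTable.load(config.correlates)
            table = _load_structure(config.construct)
            items = [i for i in table["item"] if i in matrix.item_ids]
            table = table[table["item"].isin(items)]
            structure = {r.item: r.specific_factor
                         for r in table.itertuples() if r.specific_factor}

        with stage("polychoric"):
            poly = polychoric_matrix(matrix, items)
            poly.to_frame().to_csv(out / "polychoric.csv")

        with stage("ega"):
            ega_res = ega(poly.corr, n=matrix.n_persons, item_ids=items)
            _dump({"communities": dict(zip(items, ega_res.communities)),
                   "n_communities": ega_res.n_communities,
                   "penalty": ega_res.penalty,
                   "empty_graph": ega_res.empty_graph}, out / "ega.json")

        with stage("bifactor"):
            sol = fit_bifactor_grm(
                matrix, structure, items,
                tol=config.grm_tol, max_cycles=config.grm_max_cycles)
            sol.save(out / "bifactor.json")
            lg, ls, groups = sol.loading_matrix
            idx = bifactor_indices(lg, ls, groups, items)
            _dump(idx.to_dict(), out / "indices.json")
            verdict = interpretability_rules(idx)
            _dump({"general": verdict.general_verdict,
                   "added_value": verdict.subscale_added_value,
                   "trace": verdict.trace}, out / "verdicts.json")

        with stage("score"):
            emitted: dict[str, np.ndarray] = {}
            if verdict.general_verdict == "strong":
                sc = eap_scores(sol, matrix)
                sc.save(out / "scores_general.csv")
                emitted["general"] = sc.theta
            for sub, ok in verdict.subscale_added_value.items():
                if not ok:
                    continue
                sub_items = [i for i, g in zip(items, groups) if g == sub]
                usol = fit_unidimensional_grm(
                    matrix, sub_items,
                    tol=config.grm_tol, max_cycles=config.grm_max_cycles)
                sc = eap_scores(usol, matrix.select_items(sub_items))
                sc.save(out / f"scores_{sub}.csv")
                emitted[sub] = sc.theta
            manifest["emitted_scores"] = sorted(emitted)

        if config.run_ida and correlates is not None and emitted:
            with stage("ida"):
                ida_dir = out / "ida"
                ida_dir.mkdir(exist_ok=True)
                summaries = []
                rows = []
                pid_index = {p: i for i, p in enumerate(matrix.person_ids)}
                for score_name, theta in emitted.items():
                    for corr_name in correlates.names():
                        sub = correlates.data[
                            correlates.data["name"] == corr_name]
                        ctype = sub["value_type"].iloc[0]
                        x = np.full(matrix.n_persons, np.nan)
                        for pid, v in zip(sub["person_id"], sub["value"]):
                            i = pid_index.get(str(pid))
                            if i is not None:
                                x[i] = v
                        spec = IdaModelSpec(
                            correlate_type=ctype,
                            chains=config.ida_chains,
                            draws=config.ida_draws,
                            seed=config.seed,
                        )
                        res = fit_ida_model(theta, x, matrix.study_ids, spec)
                        if isinstance(res, IdaRefusal):
                            rows.append({"score": score_name,
                                         "correlate": corr_name,
                                         "status": "refused",
                                         "reason": res.reason})
                            continue
                        try:
                            summ = effect_size_summary(res)
                        except RuntimeError as e:
                            rows.append({"score": score_name,
                                         "correlate": corr_name,
                                         "status": "not_converged",
                                         "reason": str(e)})
                            continue
                        summaries.append(summ)
                        row = {"score": score_name, "correlate": corr_name,
                               "status": "ok"}
                        row.update(summ.to_dict())
                        rows.append(row)
                pd.DataFrame(rows).to_csv(ida_dir / "summaries.csv",
                                          index=False)
                _dump(evidence_tally(summaries), ida_dir / "tally.json")
    except Exception:  # noqa: BLE001 - already recorded by the stage timer
        pass
    finally:
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["artifacts"][str(f.relative_to(out))] = _sha256(f)
        manifest["total_seconds"] = round(time.time() - t_all, 3)
        manifest["ok"] = not manifest["errors"]
        _dump(manifest, out / "manifest.json")
    return out


def render_report(run_dir: str | Path) -> Path:
    """Render a Markdown report of a run directory's artifacts."""
    run_dir = Path(run_dir)
    report = run_dir / "report.md"
    lines = ["# sensefactor run report", ""]
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        lines += ["No results found in this directory.", ""]
        report.write_text("\n".join(lines))
        return report
    manifest = json.loads(manifest_path.read_text())
    lines += [f"Seed: {manifest.get('seed')}  ",
              f"Construct: {manifest.get('construct')}  ",
              f"Status: {'ok' if manifest.get('ok') else 'with errors'}", ""]

    idx_path = run_dir / "indices.json"
    if idx_path.exists():
        idx = json.loads(idx_path.read_text())
        lines += ["## Bifactor indices", "",
                  "| index | value |", "|---|---|",
                  f"| omega_T | {idx['omega_t']:.3f} |",
                  f"| omega_H | {idx['omega_h']:.3f} |",
                  f"| ECV_G | {idx['ecv_g']:.3f} |"]
        for s in idx["omega_s"]:
            lines.append(
                f"| {s}: omega_S / omega_HS / ECV_SS | "
                f"{idx['omega_s'][s]:.3f} / {idx['omega_hs'][s]:.3f} / "
                f"{idx['ecv_ss'][s]:.3f} |")
        lines.append("")
    v_path = run_dir / "verdicts.json"
    if v_path.exists():
        v = json.loads(v_path.read_text())
        lines += ["## Verdicts", "",
                  f"General factor: **{v['general']}**", ""]
        for s, ok in v["added_value"].items():
            lines.append(f"- {s}: added value {'YES' if ok else 'NO'}")
        lines.append("")
    ida_csv = run_dir / "ida" / "summaries.csv"
    if ida_csv.exists():
        df = pd.read_csv(ida_csv)
        lines += ["## Correlate effects", "",
                  "| score | correlate | effect | median | 95% HDI | log BF | category |",
                  "|---|---|---|---|---|---|---|"]
        for r in df.itertuples():
            if r.status != "ok":
                lines.append(f"| {r.score} | {r.correlate} | — | — | — | — | "
                             f"refused |")
            else:
                lines.append(
                    f"| {r.score} | {r.correlate} | {r.effect_type} | "
                    f"{r.median:.3f} | [{r.hdi_low:.3f}, {r.hdi_high:.3f}] | "
                    f"{r.log_bf_rope:.2f} | {r.category} |")
        lines.append("")
    report.write_text("\n".join(lines))
    return report
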