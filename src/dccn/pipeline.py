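"""End-to-end orchestration: exclusions -> cumulative averages -> group
networks -> differential subnetworks -> centralities -> scores -> IRRs.

Each stage writes its artifacts before the next begins and reads its
inputs from the previous stage's files, so a run can resume from any
completed stage. The manifest records a config hash, the master seed and
a content hash per artifact; identical config + seed reproduce identical
hashes (timestamps are kept outside the hashed payload).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, centrality, data_io, diffnet, scoring, synth
from .config import validate_config
from .errors import DataError
from .network import StabilityParams, stability_edges

STAGES = (
    "ingest",
    "exclusions",
    "cumulative",
    "networks",
    "differential",
    "centrality",
    "scores",
    "assoc",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


class RunManifest:
    def __init__(self, cfg: dict):
        self.payload = {
            "package_version": __version__,
            "config_hash": config_hash(cfg),
            "seed": cfg["seed"],
            "stages": {},
        }
        self.timestamps: dict[str, float] = {}

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.payload["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)}
        }
        self.timestamps[stage] = time.time()

    def write(self, path: Path) -> None:
        doc = dict(self.payload)
        doc["timestamps"] = self.timestamps
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))

    @staticmethod
    def comparable(path: Path) -> dict:
        doc = json.loads(Path(path).read_text())
        doc.pop("timestamps", None)
        return doc


def _read_cumavg(outdir: Path) -> data_io.CumulativeIntake:
    df = pd.read_csv(outdir / "cumavg.csv").set_index("participant_id")
    foods = [c for c in df.columns if c.startswith("food_")]
    return data_io.CumulativeIntake(
        intake=df[foods].rename(columns=lambda c: c[len("food_"):]),
        energy=df["energy_kcal"],
    )


def _read_cohort_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("participant_id")
    for col in ("education_high", "exercise_regular", "on_antidiabetic_meds",
                "incident_t2d"):
        df[col] = df[col].astype(bool)
    return df


def run_all(cfg_source, resume: bool = False) -> RunManifest:
    """Execute the full workflow; returns the run manifest.

    A stage failure aborts with the stage named; artifacts from completed
    stages are retained on disk. With ``resume=True`` a stage whose output
    files already exist is skipped.
    """
    cfg = validate_config(cfg_source)
    outdir = Path(cfg["out_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg)
    seed = int(cfg["seed"])

    def done(*names: str) -> bool:
        return resume and all((outdir / n).exists() for n in names)

    current = "ingest"
    try:
        # -- ingest / simulate ------------------------------------------
        if not done("cohort_full.csv"):
            if cfg["simulate"]["enabled"]:
                sim = cfg["simulate"]
                scfg = synth.default_scenario(
                    seed=seed,
                    n_per_group={
                        "diabetic": sim["n_diabetic"],
                        "non_diabetic": sim["n_non_diabetic"],
                    },
                    n_foods=sim["n_foods"],
                    effect_log_irr_per_sd=sim["effect_log_irr_per_sd"],
                    outcome_mode=sim["outcome_mode"],
                    differential_rho=sim["differential_rho"],
                )
                intake = synth.generate_intake(scfg)
                cohort = synth.generate_outcome(intake, scfg)
                tr = synth.truth(scfg)
                (outdir / "truth.json").write_text(
                    json.dumps(
                        {
                            "differential": {
                                g: sorted(map(list, es))
                                for g, es in tr.differential.items()
                            },
                            "weights": tr.weights,
                            "effect_log_irr_per_sd": tr.effect_log_irr_per_sd,
                        },
                        indent=2,
                        sort_keys=True,
                    )
                )
                cohort[["true_score"]].to_csv(outdir / "true_scores.csv")
                data_io.write_cohort(
                    cohort[list(data_io.COHORT_COLUMNS)], intake,
                    outdir / "cohort_full.csv",
                )
            else:
                cohort, intake = data_io.read_cohort(
                    cfg["input"]["cohort_csv"],
                    food_columns=cfg["input"]["food_columns"],
                    food_prefix=cfg["input"]["food_prefix"],
                )
                data_io.write_cohort(cohort, intake, outdir / "cohort_full.csv")
        manifest.record("ingest", [outdir / "cohort_full.csv"])

        # -- exclusions --------------------------------------------------
        current = "exclusions"
        cohort, intake = data_io.read_cohort(outdir / "cohort_full.csv")
        if not done("cohort_included.csv", "exclusion_log.json"):
            kept, log = data_io.apply_exclusions(
                cohort, intake,
                energy_low_pct=cfg["exclusions"]["energy_low"],
                energy_high_pct=cfg["exclusions"]["energy_high"],
            )
            log.to_json(outdir / "exclusion_log.json")
            data_io.write_cohort(kept, intake.restrict(kept.index),
                                 outdir / "cohort_included.csv")
        manifest.record(
            "exclusions",
            [outdir / "cohort_included.csv", outdir / "exclusion_log.json"],
        )

        # -- cumulative averages ----------------------------------------
        current = "cumulative"
        cohort, intake = data_io.read_cohort(outdir / "cohort_included.csv")
        if not done("cumavg.csv"):
            cum = data_io.cumulative_average(intake, cohort,
                                             design=cfg["intake"]["design"])
            out = cum.intake.rename(columns=lambda c: "food_" + c)
            out["energy_kcal"] = cum.energy
            out.to_csv(outdir / "cumavg.csv", float_format="%.17g")
        manifest.record("cumulative", [outdir / "cumavg.csv"])

        # -- group networks ---------------------------------------------
        current = "networks"
        cum = _read_cumavg(outdir)
        groups = {
            "diabetic": cohort.index[cohort["incident_t2d"]],
            "non_diabetic": cohort.index[~cohort["incident_t2d"]],
        }
        params = StabilityParams(
            n_iter=cfg["network"]["n_iter"],
            subsample_frac=cfg["network"]["subsample_frac"],
            r_threshold=cfg["network"]["r_threshold"],
            alpha=cfg["network"]["alpha"],
            with_replacement=cfg["network"]["with_replacement"],
            seed=seed,
        )
        nets = {}
        net_files = []
        for g, ids in groups.items():
            path = outdir / f"edges_{g}.csv"
            net_files.append(path)
            if done(path.name):
                nets[g] = data_io.read_network(path)
                continue
            cov = pd.DataFrame(
                {
                    "energy_kcal": cum.energy.loc[ids],
                    "sex_female": (cohort.loc[ids, "sex"] == "female").astype(float),
                }
            )
            net = stability_edges(cum.intake.loc[ids], cov, params, group=g,
                                  keep_iterations=False)
            nets[g] = net.to_networkx()
            data_io.write_network(net, path, fmt="edge_csv")
            data_io.write_network(net, outdir / f"network_{g}.graphml",
                                  fmt="graphml")
        manifest.record("networks", net_files)

        # -- differential subnetworks -----------------------------------
        current = "differential"
        diff = diffnet.differential(nets["diabetic"], nets["non_diabetic"])
        exclusive = {
            "diabetic": diff.group_a_exclusive,
            "non_diabetic": diff.group_b_exclusive,
        }
        diff_files = []
        for g, sub in exclusive.items():
            path = outdir / f"diff_{g}.csv"
            data_io.write_network(sub, path, fmt="edge_csv")
            data_io.write_network(sub, outdir / f"diff_{g}.graphml",
                                  fmt="graphml")
            diff_files.append(path)
        summary = {
            g: diffnet.summarize(sub).as_dict() if sub.number_of_nodes() else None
            for g, sub in exclusive.items()
        }
        summary["n_shared_edges"] = len(diff.shared_edges)
        (outdir / "diff_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        diff_files.append(outdir / "diff_summary.json")
        manifest.record("differential", diff_files)

        # -- centralities ------------------------------------------------
        current = "centrality"
        weight_maps = {}
        cen_files = []
        for g, sub in exclusive.items():
            path = outdir / f"centrality_{g}.csv"
            cen_files.append(path)
            if sub.number_of_nodes() == 0:
                weight_maps[g] = {}
                path.write_text("food,integrated\n")
                continue
            table = centrality.centralities(sub)
            table["role"] = centrality.classify_roles(table)
            table.rename_axis("food").to_csv(path, float_format="%.17g")
            weight_maps[g] = centrality.centrality_weights(table)
        manifest.record("centrality", cen_files)

        # -- scores ------------------------------------------------------
        current = "scores"
        scores = scoring.transfer(
            weight_maps["diabetic"],
            weight_maps["non_diabetic"],
            cum,
            policy=cfg["score"]["policy"],
            quantile_method=cfg["score"]["quantile_method"],
        )
        labels, _ = assoc.quartile_assign(scores["d_ccn"])
        scores["quartile"] = labels.astype(str)
        data_io.write_scores(scores, outdir / "scores.csv")
        manifest.record("scores", [outdir / "scores.csv"])

        # -- association -------------------------------------------------
        current = "assoc"
        data = cohort.join(cum.energy)
        result, _ = assoc.fit_quartile_irr(
            data, scores["d_ccn"],
            adjust=cfg["assoc"]["adjust"], smoking=cfg["assoc"]["smoking"],
        )
        (outdir / "irr.json").write_text(
            json.dumps(result.as_dict(), indent=2, sort_keys=True)
        )
        manifest.record("assoc", [outdir / "irr.json"])
    except Exception as exc:
        raise type(exc)(f"[stage {current}] {exc}") from exc

    manifest.write(outdir / "manifest.json")
    return manifest
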