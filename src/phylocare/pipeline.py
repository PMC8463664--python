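"""End-to-end analysis pipeline.

Stages, in the order the method runs: input validation/audit -> trait coding
-> equal-rates marginal ancestral state reconstruction per discrete trait ->
pairwise phylogenetic regressions with FDR adjustment -> phylogenetic
logistic regressions -> correlated-evolution (independent vs dependent vs
constrained) stepping-stone Bayes factors and posterior transition rates.

Two scale presets are provided.  ``desk`` finishes a 220-species dataset in a
few minutes on one CPU and is the default for interactive work and the test
suite; ``paper`` mirrors the published chain settings (stepping-stone with
100 stones x 10,000 iterations; logistic-regression chains of 2e7 iterations
with burn-in 1,000 and thinning 500) and is hours-long.  All randomness flows
from the single config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mk, pagel, regression, traits as traits_mod
from .trees import PhyloTree, prune_to_taxa, read_newick, tipset_hashes

__all__ = ["AnalysisConfig", "PipelineError", "run_all", "validate_inputs", "PRESETS"]

log = logging.getLogger("phylocare")

PRESETS = {
    "desk": {
        "pglmm": dict(n_iter=6000, burn_in=1000, thin=5, n_chains=2),
        "pagel_ss": dict(n_stones=10, iters_per_stone=1000),
        "pagel_mcmc": dict(n_iter=4000, burn_in=800),
    },
    "paper": {
        "pglmm": dict(n_iter=20_000_000, burn_in=1000, thin=500, n_chains=4),
        "pagel_ss": dict(n_stones=100, iters_per_stone=10_000),
        "pagel_mcmc": dict(n_iter=100_000, burn_in=10_000),
    },
}

DISCRETE_TRAITS = [
    "conspicuous",
    "caregiver_female",
    "habitat_far",
    "transporter_female",
    "phytotelm_breeder",
    "cannibalism",
]

CONTINUOUS_TRAITS = [
    "coloration_score",
    "ssd",
    "log_clutch_size",
    "log_egg_size",
    "log_tadpole_size",
    "log_n_tadpoles",
    "log1p_alkaloids",
]

PGLMM_RESPONSES = [
    "phytotelm_breeder",
    "cannibalism",
    "alkaloids_present",
    "transporter_female",
    "conspicuous",
    "habitat_far",
    "caregiver_female",
]

PGLMM_PREDICTORS = [
    "coloration_score",
    "ssd",
    "log_n_tadpoles",
    "residual_tadpole_size",
]

PAGEL_PAIRS = [("conspicuous", "phytotelm_breeder"), ("alkaloids_present", "phytotelm_breeder")]


@dataclass
class AnalysisConfig:
    tree_path: str
    traits_path: str
    out_dir: str
    preset: str = "desk"
    seed: int = 1
    overrides: dict = field(default_factory=dict)

    def settings(self) -> dict:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        base = {k: dict(v) for k, v in PRESETS[self.preset].items()}
        for key, val in self.overrides.items():
            if key in base and isinstance(val, dict):
                base[key].update(val)
            else:
                base[key] = val
        return base

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                dict(
                    tree_path=self.tree_path,
                    traits_path=self.traits_path,
                    out_dir=self.out_dir,
                    preset=self.preset,
                    seed=self.seed,
                    overrides=self.overrides,
                ),
                fh,
            )


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(tree: PhyloTree, raw: pd.DataFrame) -> dict:
    """Report-only audit: tree/table species mismatches and missingness."""
    tree_set = set(tree.tip_labels)
    table_set = set(raw.index)
    missingness = {}
    for col in raw.columns:
        vals = raw[col].astype(object)
        blank = vals.isna() | vals.isin(["", "NA"])
        missingness[col] = float(blank.mean())
    return {
        "n_tree_tips": len(tree_set),
        "n_table_species": len(table_set),
        "in_tree_not_table": sorted(tree_set - table_set),
        "in_table_not_tree": sorted(table_set - tree_set),
        "missingness": missingness,
    }


def _usable_n(coded: pd.DataFrame, tree: PhyloTree) -> dict:
    out = {}
    tree_set = set(tree.tip_labels)
    for resp in PGLMM_RESPONSES:
        preds = [p for p in PGLMM_PREDICTORS if p != resp and p in coded.columns]
        cols = [resp] + preds
        cols = [c for c in cols if c in coded.columns]
        sub = coded[cols].dropna()
        out[resp] = int(sum(1 for s in sub.index if s in tree_set))
    return out


def _seeds(seed: int, n: int) -> list:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_all(config: AnalysisConfig) -> dict:
    """Run every stage; returns a manifest of written outputs and summaries."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = config.settings()
    t_start = time.time()
    manifest = {"stages": {}, "outputs": [], "seed": config.seed, "preset": config.preset}

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    def record(stage, payload=None):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t_start, 2)}
        log.info("stage %s done (%.1fs)", stage, time.time() - t_start)
        if payload:
            manifest["stages"][stage].update(payload)

    try:
        stage = "load_inputs"
        tree = read_newick(config.tree_path)
        raw = traits_mod.read_trait_table(config.traits_path)
        record(stage)

        stage = "validate"
        audit = validate_inputs(tree, raw)
        record(stage)

        stage = "coding"
        coding = traits_mod.code_trait_table(raw, tree=tree)
        if not set(tree.tip_labels) & set(raw.index):
            raise ValueError("no species shared between tree and trait table")
        coded = coding.coded
        coded["log1p_alkaloids"] = np.log1p(coded["alkaloid_level"])
        coded.to_csv(out_dir / "coded_traits.csv")
        coding.exclusions.to_csv(out_dir / "exclusions.csv", index=False)
        audit["usable_n"] = _usable_n(coded, tree)
        with open(out_dir / "data_audit.json", "w") as fh:
            json.dump(audit, fh, indent=2)
        manifest["outputs"] += ["coded_traits.csv", "exclusions.csv", "data_audit.json"]
        record(stage, {"n_coded": len(coded), "n_excluded": len(coding.exclusions)})

        stage = "asr"
        for trait in DISCRETE_TRAITS:
            if trait not in coded.columns:
                continue
            obs = coded[trait].dropna()
            obs = obs.loc[[s for s in obs.index if s in set(tree.tip_labels)]]
            if len(obs) < 3 or obs.nunique() < 2:
                log.warning("skipping ASR for %s: insufficient variation", trait)
                continue
            sub = prune_to_taxa(tree, list(obs.index))
            states = np.array([obs[s] for s in sub.tip_labels])
            fit = mk.fit_er(sub, states, k=2)
            asr = mk.marginal_asr(sub, states, fit.model)
            hashes = tipset_hashes(sub)
            rows = []
            for node in asr.internal_nodes:
                rows.append(
                    {
                        "node": int(node),
                        "clade": hashes[node],
                        "p_state0": asr.node_probs[node, 0],
                        "p_state1": asr.node_probs[node, 1],
                    }
                )
            df = pd.DataFrame(rows)
            df.attrs["q_hat"] = fit.model.q
            df.to_csv(out_dir / f"asr_{trait}.csv", index=False)
            manifest["outputs"].append(f"asr_{trait}.csv")
        record(stage)

        stage = "pairwise_pgls"
        cont = coded[[c for c in CONTINUOUS_TRAITS if c in coded.columns]]
        table3 = regression.pairwise_pgls_matrix(cont, tree)
        table3.to_csv(out_dir / "pairwise_regressions.csv", index=False)
        manifest["outputs"].append("pairwise_regressions.csv")
        record(stage)

        stage = "pglmm"
        pg_seeds = _seeds(config.seed, len(PGLMM_RESPONSES))
        rows = []
        for resp, s in zip(PGLMM_RESPONSES, pg_seeds):
            preds = [p for p in PGLMM_PREDICTORS if p != resp]
            if resp == "conspicuous":
                preds = [p for p in preds if p != "coloration_score"]
            try:
                spec = regression.PglmmSpec(
                    response=resp, predictors=preds, seed=s, **settings["pglmm"]
                )
                res = regression.pglmm_logistic(spec, coded, tree)
            except ValueError as exc:
                log.warning("pglmm for %s skipped: %s", resp, exc)
                continue
            row = {"response": resp, "N": res.n, "separation": res.separation_warning}
            for i, pname in enumerate(["intercept"] + preds):
                coef = res.coefficients.iloc[i]
                row[f"beta_{i}"] = coef["mean"]
                row[f"p_{i}"] = coef["pMCMC"]
                row[f"rhat_{i}"] = coef["rhat"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "logistic_regressions.csv", index=False)
        manifest["outputs"].append("logistic_regressions.csv")
        record(stage)

        stage = "pagel"
        bf_out = {}
        tr_rows = []
        pagel_seeds = _seeds(config.seed + 1, 4 * len(PAGEL_PAIRS))
        si = 0
        for traitA, traitB in PAGEL_PAIRS:
            pair_key = f"{traitA}__vs__{traitB}"
            sub = coded[[traitA, traitB]]
            sub = sub.loc[[s for s in sub.index if s in set(tree.tip_labels)]]
            has_any = sub.notna().any(axis=1)
            sub = sub.loc[has_any]
            ptree = prune_to_taxa(tree, list(sub.index))
            A = np.array([sub[traitA].get(s, np.nan) for s in ptree.tip_labels])
            B = np.array([sub[traitB].get(s, np.nan) for s in ptree.tip_labels])
            ss_cfg = settings["pagel_ss"]
            results = {}
            for model in ("independent", "dependent", "constrained"):
                results[model] = pagel.stepping_stone_ml(
                    ptree, A, B, model, seed=pagel_seeds[si], **ss_cfg
                )
                si += 1
            bf_dep = pagel.log_bayes_factor(results["dependent"], results["independent"])
            bf_con = pagel.log_bayes_factor(results["constrained"], results["independent"])
            bf_out[pair_key] = {
                "n_species": int(len(sub)),
                "ln_ml": {m: results[m].log_ml for m in results},
                "logBF_dependent_vs_independent": bf_dep.log_bf,
                "band_dependent_vs_independent": bf_dep.band,
                "logBF_constrained_vs_independent": bf_con.log_bf,
                "band_constrained_vs_independent": bf_con.band,
                "raw_lnBF_dependent_vs_independent": bf_dep.raw_log_bf,
            }
            chain = pagel.mcmc_sample(
                ptree, A, B, "constrained", seed=pagel_seeds[si], **settings["pagel_mcmc"]
            )
            si += 1
            summary = pagel.transition_summary(chain)
            for qname, row in summary.table.iterrows():
                tr_rows.append(
                    {
                        "pair": pair_key,
                        "parameter": qname,
                        "mean": row["mean"],
                        "median": row["median"],
                        "q2.5": row["q2.5"],
                        "q97.5": row["q97.5"],
                    }
                )
            for rname, val in summary.ratios.items():
                bf_out[pair_key][f"ratio_{rname}"] = val
        with open(out_dir / "bayes_factors.json", "w") as fh:
            json.dump(bf_out, fh, indent=2)
        pd.DataFrame(tr_rows).to_csv(out_dir / "transition_rates.csv", index=False)
        manifest["outputs"] += ["bayes_factors.json", "transition_rates.csv"]
        record(stage, {"bayes_factors": bf_out})

        manifest["elapsed_s"] = round(time.time() - t_start, 2)
        import importlib.metadata as ilmd

        try:
            manifest["version"] = ilmd.version("phylocare")
        except ilmd.PackageNotFoundError:
            manifest["version"] = "unknown"
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
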