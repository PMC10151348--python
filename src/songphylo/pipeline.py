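"""End-to-end orchestration: configuration, staged runs, manifests, report.

Each stage reads its upstream artifacts from the output directory, writes its
own artifacts plus a JSON manifest entry (inputs' checksums, seed, package
version), and is idempotent given identical inputs. The stages mirror the
analysis order: synth -> impute -> pca -> overlap -> classify -> associate ->
signal -> report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustic_features import (
    FEATURE_NAMES,
    FUND_FEATURES,
    validate_feature_table,
)
from .association import associate, log_transform, stahel_constant
from .classification import (
    class_priors_from_motifs,
    evaluate,
    permutation_importance,
    select_features,
    train_forest,
)
from .feature_space import pca_fit, ripca_impute
from .hypervolume import fit_boundary, overlap_indices, symmetry_test
from .phylo_signal import (
    build_distance_matrices,
    cluster_dendrogram,
    fmi_test,
    pp_mantel,
    two_step_signal,
)
from .synth import SynthSpec, synth_feature_table, synth_morphometrics, species_frequency_traits
from .trees import Phylogeny, example_tree, simulate_tree

__all__ = ["RunConfig", "run_stage", "run_all", "report", "STAGES"]

STAGES = ["synth", "impute", "pca", "overlap", "classify", "associate", "signal", "report"]


@dataclass
class RunConfig:
    """All knobs for a reproducible pipeline run."""

    outdir: str = "songphylo_run"
    seed: int = 0
    tree_file: str | None = None       # None -> bundled example topology
    synth: dict = field(default_factory=dict)     # SynthSpec overrides
    n_pcs: int = 3
    svm_nu: float = 0.01
    svm_gamma: float = 0.5
    mc_samples: int = 20_000
    mc_iterations: int = 10
    n_trees: int = 200
    importance_iterations: int = 10
    n_perm: int = 1000
    n_sim: int = 1000
    alpha: float = 0.05
    fmi_k: int = 3
    pp_k_influence: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def spec(self) -> SynthSpec:
        return SynthSpec(seed=self.seed, **self.synth)

    def tree(self) -> Phylogeny:
        if self.tree_file:
            return Phylogeny.from_file(self.tree_file)
        return example_tree()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(outdir: Path, stage: str, inputs: list[Path], seed: int) -> None:
    entry = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "inputs": {p.name: _checksum(p) for p in inputs if p.exists()},
    }
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = entry
    path.write_text(json.dumps(manifest, indent=1))


def _need(outdir: Path, name: str, producer: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(f"missing artifact {name}; run the '{producer}' stage first")
    return p


def _load_features(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature CSV schema invalid; missing column(s): {missing}")
    return table


def run_stage(name: str, config: RunConfig) -> dict:
    """Run one pipeline stage; returns a small dict of headline numbers."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = config.tree()
    rng = np.random.default_rng(config.seed)
    info: dict = {"stage": name}

    if name == "synth":
        spec = config.spec()
        table = synth_feature_table(spec, tree)
        table.to_csv(outdir / "features_raw.csv", index=False)
        traits = species_frequency_traits(spec, tree, np.random.default_rng(spec.seed))
        morpho = synth_morphometrics(tree, traits, seed=spec.seed)
        morpho.to_csv(outdir / "morphometrics.csv")
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        _manifest(outdir, name, [], config.seed)
        info["n_syllables"] = len(table)

    elif name == "impute":
        table = _load_features(_need(outdir, "features_raw.csv", "synth"))
        imputed = ripca_impute(table)
        validate_feature_table(imputed)
        imputed.to_csv(outdir / "features_imputed.csv", index=False)
        _manifest(outdir, name, [outdir / "features_raw.csv"], config.seed)
        info["n_missing_before"] = int(table[FUND_FEATURES].isna().sum().sum())

    elif name == "pca":
        table = _load_features(_need(outdir, "features_imputed.csv", "impute"))
        model = pca_fit(table)
        model.to_json(outdir / "pca_model.json")
        scores = table.copy()
        for i in range(config.n_pcs):
            scores[f"pc{i + 1}"] = model.scores.iloc[:, i].to_numpy()
        scores.to_csv(outdir / "features_scored.csv", index=False)
        info["variance_explained_first3"] = float(model.explained_variance_ratio[: config.n_pcs].sum())
        _manifest(outdir, name, [outdir / "features_imputed.csv"], config.seed)

    elif name == "overlap":
        scored = pd.read_csv(_need(outdir, "features_scored.csv", "pca"))
        pc_cols = [f"pc{i + 1}" for i in range(config.n_pcs)]
        models = {}
        for s, block in scored.groupby("species", sort=False):
            models[s] = fit_boundary(
                block[pc_cols].to_numpy(), species=s, nu=config.svm_nu, gamma=config.svm_gamma
            )
        ov = overlap_indices(
            models, n_samples=config.mc_samples, iterations=config.mc_iterations,
            seed=int(rng.integers(2**31 - 1)),
        )
        ov.jaccard.to_csv(outdir / "overlap_jaccard.csv")
        ov.directional.to_csv(outdir / "overlap_directional.csv")
        rs, p, n_pairs = symmetry_test(ov.directional)
        info.update({"symmetry_rs": rs, "symmetry_p": p, "n_pairs": n_pairs})
        _manifest(outdir, name, [outdir / "features_scored.csv"], config.seed)

    elif name == "classify":
        table = _load_features(_need(outdir, "features_imputed.csv", "impute"))
        priors = class_priors_from_motifs(table)
        imp = permutation_importance(
            table, n_trees=config.n_trees, iterations=config.importance_iterations,
            seed=int(rng.integers(2**31 - 1)),
        )
        selected = select_features(imp)
        imp.delta_errors.to_csv(outdir / "importance_delta_errors.csv", index=False)
        (outdir / "selected_features.json").write_text(json.dumps(selected, indent=1))
        model = train_forest(
            table, selected, priors, n_trees=config.n_trees,
            seed=int(rng.integers(2**31 - 1)),
        )
        cstats = evaluate(model)
        cstats.counts.to_csv(outdir / "confusion_counts.csv")
        cstats.row_percent.to_csv(outdir / "confusion_percent.csv")
        cstats.misclassification.to_csv(outdir / "misclassification.csv")
        info.update({
            "selected": selected,
            "oob_accuracy": 1.0 - model.oob_error,
            "weighted_f1": cstats.weighted_f1,
        })
        _manifest(outdir, name, [outdir / "features_imputed.csv"], config.seed)

    elif name == "associate":
        h = pd.read_csv(_need(outdir, "overlap_directional.csv", "overlap"), index_col=0)
        r = pd.read_csv(_need(outdir, "misclassification.csv", "classify"), index_col=0)
        r = r.loc[h.index, h.columns]
        from .association import directed_pairs

        hv, rv = directed_pairs(h), directed_pairs(r)
        c_h, c_r = stahel_constant(hv), stahel_constant(rv)
        r_corr, p, n_pairs = associate(log_transform(hv, c_h), log_transform(rv, c_r))
        payload = {"c_H": c_h, "c_R": c_r, "r": r_corr, "p": p, "N": n_pairs}
        (outdir / "association.json").write_text(json.dumps(payload, indent=1))
        info.update(payload)
        _manifest(outdir, name, [outdir / "overlap_directional.csv", outdir / "misclassification.csv"], config.seed)

    elif name == "signal":
        scored = pd.read_csv(_need(outdir, "features_scored.csv", "pca"))
        pc_cols = [f"pc{i + 1}" for i in range(config.n_pcs)]
        matrices = build_distance_matrices(scored, pc_cols)
        results = two_step_signal(
            matrices, tree, alpha=config.alpha, n_perm=config.n_perm,
            n_sim=config.n_sim, seed=int(rng.integers(2**31 - 1)),
        )
        # FMI of each PC dendrogram against the phylogeny, cut at k clusters
        phylo_dendro = cluster_dendrogram(tree.patristic_matrix())
        fmi_rows = {}
        for col in pc_cols:
            res = fmi_test(cluster_dendrogram(matrices[col]), phylo_dendro, k=config.fmi_k)
            fmi_rows[col] = {"fmi": res.fmi, "p": res.p}
        results["fmi"] = [fmi_rows[c]["fmi"] for c in results.index]
        results["fmi_p"] = [fmi_rows[c]["p"] for c in results.index]
        morpho_path = outdir / "morphometrics.csv"
        if morpho_path.exists():
            morpho = pd.read_csv(morpho_path, index_col=0)
            morpho_d = {
                col: pd.DataFrame(
                    np.abs(morpho[col].to_numpy()[:, None] - morpho[col].to_numpy()[None, :]),
                    index=morpho.index, columns=morpho.index,
                )
                for col in morpho.columns
            }
            for col, dm in morpho_d.items():
                res = pp_mantel(
                    matrices[pc_cols[0]], dm, tree, k_influence=config.pp_k_influence,
                    n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)),
                )
                info[f"pp_{col}_r"] = res.r
                info[f"pp_{col}_p"] = res.p
        else:
            info["pp_mantel"] = "skipped (no morphometrics)"
        results.to_csv(outdir / "signal_results.csv")
        info["significant"] = list(results.index[results["significant"]])
        _manifest(outdir, name, [outdir / "features_scored.csv"], config.seed)

    elif name == "report":
        info["report_path"] = str(report(outdir))

    else:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    return info


def run_all(config: RunConfig) -> dict:
    """Run every stage in order; returns per-stage headline numbers."""
    return {name: run_stage(name, config) for name in STAGES}


def report(results_dir) -> Path:
    """Render a deterministic markdown summary of a completed run."""
    outdir = Path(results_dir)
    lines = ["# songphylo run report", ""]

    def table_section(title, fname, floatfmt="{:.4g}"):
        p = outdir / fname
        lines.append(f"## {title}")
        if not p.exists():
            lines.append("_skipped (artifact missing)_")
            lines.append("")
            return
        df = pd.read_csv(p, index_col=0)
        lines.append(df.to_markdown(floatfmt=".4g") if hasattr(df, "to_markdown") else df.to_string())
        lines.append("")

    pca_json = outdir / "pca_model.json"
    lines.append("## Principal components")
    if pca_json.exists():
        model = json.loads(pca_json.read_text())
        ev = np.array(model["eigenvalues"])
        share = 100 * ev / ev.sum()
        lines.append("| component | eigenvalue | % variance |")
        lines.append("|---|---|---|")
        for i in range(min(5, len(ev))):
            lines.append(f"| PC{i + 1} | {ev[i]:.3f} | {share[i]:.2f} |")
    else:
        lines.append("_skipped (artifact missing)_")
    lines.append("")
    table_section("Hypervolume overlap (Jaccard)", "overlap_jaccard.csv")
    table_section("Hypervolume overlap (directional)", "overlap_directional.csv")
    table_section("Feature importance (delta error, per iteration)", "importance_delta_errors.csv")
    table_section("Confusion matrix (%)", "confusion_percent.csv")
    table_section("Phylogenetic signal", "signal_results.csv")
    assoc = outdir / "association.json"
    lines.append("## Overlap vs misclassification")
    if assoc.exists():
        lines.append("```json")
        lines.append(assoc.read_text())
        lines.append("```")
    else:
        lines.append("_skipped (artifact missing)_")
    lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
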