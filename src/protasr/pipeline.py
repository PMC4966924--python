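"""Job orchestration: the staged analysis pipeline over an
alignment-method x model grid.

A job validates its input alignments, compares them residue-by-residue,
fits every model on every alignment (exhaustive ML search at desk
scale, or fixed/constrained topologies), computes aLRT branch support,
reconstructs ancestors on every outgroup-rooted ML tree, and finishes
with the robustness report and per-branch candidate substitutions.
Every product is a plain-text file (FASTA, Newick, TSV, JSON); the job
state is persisted after each stage so an interrupted or partially
deleted job resumes at the first stage whose products are missing.
All randomness flows from ``JobConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aligncompare
from .alignment import Alignment, read_fasta, write_fasta
from .ancestral import (marginal_posteriors, ml_sequence, sample_sequences,
                        support_summary)
from .likelihood import (TreeLikelihood, aic_select, alrt_branch_support,
                         exhaustive_ml_search, MAX_EXHAUSTIVE_TAXA)
from .models import parse_model_spec
from .robustness import (RobustnessGrid, branch_path_mutations,
                         robustness_report, root_by_outgroup)
from .tree import PhyloTree, read_newick, write_newick

STAGES = [
    "aligned-input-validation",
    "alignment-comparison",
    "model-fitting",
    "tree-inference",
    "branch-support",
    "ancestral-reconstruction",
    "robustness-and-trajectories",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class JobConfig:
    """Configuration of one analysis job."""

    alignments: list  # list[Alignment]
    outgroup: set
    model_specs: list = field(default_factory=lambda: ["LG", "LG+G"])
    constraint_tree: PhyloTree | None = None
    ncat: int = 4
    seed: int = 0
    mask_threshold: float | None = None  # None: no masking
    column_scores: dict = field(default_factory=dict)  # name -> ColumnScores
    n_samples: int = 10  # Bayesian-sampled sequences per node
    confident_threshold: float = 0.8

    def validate(self) -> None:
        if not self.alignments:
            raise PipelineError("no alignments configured")
        if not self.model_specs:
            raise PipelineError("model grid is empty")
        names = [a.name for a in self.alignments]
        if len(set(names)) != len(names):
            raise PipelineError("alignment names must be unique")
        taxa = set(self.alignments[0].taxa)
        for a in self.alignments[1:]:
            if set(a.taxa) != taxa:
                raise PipelineError(
                    f"alignment {a.name!r} has different taxa")
        og = set(self.outgroup)
        if not og or not og < taxa:
            raise PipelineError(
                "outgroup must be a nonempty proper subset of the taxa")
        if len(taxa) < 4:
            raise PipelineError("need at least 4 taxa")


@dataclass
class JobState:
    """Per-stage status of a job directory."""

    stages: dict  # stage -> {"pending", "running", "complete", "failed"}

    @property
    def percent_complete(self) -> float:
        done = sum(1 for s in STAGES if self.stages.get(s) == "complete")
        return 100.0 * done / len(STAGES)

    @property
    def stage(self) -> str:
        for s in STAGES:
            if self.stages.get(s) != "complete":
                return s
        return "done"

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages,
                           "percent_complete": self.percent_complete,
                           "stage": self.stage},
                          indent=2, sort_keys=True)


def _save_state(outdir: str, state: JobState) -> None:
    with open(os.path.join(outdir, "jobstate.json"), "w") as fh:
        fh.write(state.to_json() + "\n")


def job_status(outdir: str) -> JobState:
    """Read the persisted state of a job directory."""
    path = os.path.join(outdir, "jobstate.json")
    if not os.path.exists(path):
        raise PipelineError(f"{outdir!r} is not an initialized job directory")
    with open(path) as fh:
        data = json.load(fh)
    return JobState(stages=data["stages"])


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _cell_tag(aln_name: str, spec: str) -> str:
    return f"{aln_name}__{spec.replace('+', 'p').replace('{', '').replace('}', '').replace('=', '')}"


def run_pipeline(config: JobConfig, outdir: str) -> JobState:
    """Execute (or resume) the staged pipeline into ``outdir``.

    A stage whose product files already exist is loaded, not
    recomputed, so deleting downstream products and rerunning resumes
    at the first missing stage. Two runs with the same config and seed
    produce byte-identical products.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    state = JobState(stages={s: "pending" for s in STAGES})
    cells = [(a.name, spec) for a in config.alignments
             for spec in config.model_specs]
    ctx: dict = {"alignments": {a.name: a for a in config.alignments}}

    runners = {
        "aligned-input-validation": _stage_validate,
        "alignment-comparison": _stage_compare,
        "model-fitting": _stage_modelfit,
        "tree-inference": _stage_trees,
        "branch-support": _stage_support,
        "ancestral-reconstruction": _stage_ancestors,
        "robustness-and-trajectories": _stage_robustness,
    }
    for stage in STAGES:
        state.stages[stage] = "running"
        _save_state(outdir, state)
        try:
            runners[stage](config, outdir, ctx, cells)
        except Exception:
            state.stages[stage] = "failed"
            _save_state(outdir, state)
            raise
        state.stages[stage] = "complete"
        _save_state(outdir, state)
    return state


# -- stages ------------------------------------------------------------


def _stage_validate(config, outdir, ctx, cells):
    d = os.path.join(outdir, "alignments")
    os.makedirs(d, exist_ok=True)
    for aln in config.alignments:
        path = os.path.join(d, f"{aln.name}.fasta")
        if os.path.exists(path):
            loaded = read_fasta(path, aligned=True, name=aln.name)
            ctx["alignments"][aln.name] = loaded
            continue
        if config.mask_threshold is not None:
            scores = config.column_scores.get(
                aln.name, aligncompare.uniform_scores(aln))
            masked, kept = aligncompare.apply_column_mask(
                aln, scores, config.mask_threshold)
            ctx["alignments"][aln.name] = masked
            _write_json(os.path.join(d, f"{aln.name}.kept_columns.json"),
                        {"kept_columns": kept})
            aln = masked
        if aln.ncols < 2:
            raise PipelineError(
                f"alignment {aln.name!r} has fewer than 2 columns after "
                "masking")
        write_fasta(aln, path)


def _stage_compare(config, outdir, ctx, cells):
    d = os.path.join(outdir, "alignment_compare")
    os.makedirs(d, exist_ok=True)
    alns = list(ctx["alignments"].values())
    if len(alns) < 2:
        _write_json(os.path.join(d, "consistency.json"),
                    {"note": "single alignment; nothing to compare"})
        return
    rmap = aligncompare.build_residue_map(alns)
    out = {}
    for ref in rmap.names:
        scores = aligncompare.consistency_score(rmap, ref)
        out[ref] = [None if np.isnan(s) else round(float(s), 10)
                    for s in scores]
    _write_json(os.path.join(d, "consistency.json"),
                {"statistic": "mean of max site-identity fractions "
                              "(package-defined summary)",
                 "per_column_scores": out})
    ctx["residue_map"] = rmap


def _stage_modelfit(config, outdir, ctx, cells):
    dt = os.path.join(outdir, "trees")
    dm = os.path.join(outdir, "modelfit")
    os.makedirs(dt, exist_ok=True)
    os.makedirs(dm, exist_ok=True)
    ctx["results"] = {}
    for aln_name, aln in ctx["alignments"].items():
        table_path = os.path.join(dm, f"{aln_name}.tsv")
        rows = []
        for spec in config.model_specs:
            tree_path = os.path.join(dt, f"{_cell_tag(aln_name, spec)}.nwk")
            meta_path = os.path.join(dt, f"{_cell_tag(aln_name, spec)}.json")
            if os.path.exists(tree_path) and os.path.exists(meta_path):
                with open(meta_path) as fh:
                    meta = json.load(fh)
                tree = read_newick(tree_path)
                model = parse_model_spec(spec, alignment=aln,
                                         default_ncat=config.ncat)
                if meta.get("alpha") is not None:
                    model = model.with_alpha(meta["alpha"])
                res = TreeLikelihood(aln, tree, model).fit(optimize=())
                res.n_topologies_evaluated = meta.get("n_topologies")
            else:
                model = parse_model_spec(spec, alignment=aln,
                                         default_ncat=config.ncat)
                if len(aln.taxa) <= MAX_EXHAUSTIVE_TAXA:
                    res = exhaustive_ml_search(
                        aln, model, constraint=config.constraint_tree)
                elif config.constraint_tree is not None:
                    res = TreeLikelihood(
                        aln, config.constraint_tree, model).fit()
                else:
                    raise PipelineError(
                        f"{len(aln.taxa)} taxa exceed the exhaustive "
                        "search cap; provide a constraint tree")
                with open(tree_path, "w") as fh:
                    fh.write(write_newick(res.tree) + "\n")
                _write_json(meta_path, {
                    "alpha": res.subst_model.alpha,
                    "lnL": res.lnL,
                    "n_topologies": getattr(res, "n_topologies_evaluated",
                                            None),
                })
            ctx["results"][(aln_name, spec)] = res
            rows.append({"alignment": aln_name, "model": spec,
                         "lnL": res.lnL, "k": res.n_parameters,
                         "AIC": res.aic})
        df = pd.DataFrame(rows)
        df["best"] = df["AIC"] == df["AIC"].min()
        if df["best"].sum() > 1:  # tie-break: fewer params, then name
            order = df.sort_values(["AIC", "k", "model"],
                                   kind="mergesort").index
            df["best"] = False
            df.loc[order[0], "best"] = True
        _write_tsv(table_path, df)
        _write_json(os.path.join(dm, f"{aln_name}.json"),
                    df.to_dict(orient="records"))


def _stage_trees(config, outdir, ctx, cells):
    d = os.path.join(outdir, "trees_rooted")
    os.makedirs(d, exist_ok=True)
    ctx["rooted"] = {}
    for (aln_name, spec), res in ctx["results"].items():
        path = os.path.join(d, f"{_cell_tag(aln_name, spec)}.nwk")
        rooted = root_by_outgroup(res.tree, config.outgroup)
        ctx["rooted"][(aln_name, spec)] = rooted
        if not os.path.exists(path):
            with open(path, "w") as fh:
                fh.write(write_newick(rooted) + "\n")


def _stage_support(config, outdir, ctx, cells):
    d = os.path.join(outdir, "support")
    os.makedirs(d, exist_ok=True)
    for (aln_name, spec), res in ctx["results"].items():
        tag = _cell_tag(aln_name, spec)
        jpath = os.path.join(d, f"{tag}.json")
        npath = os.path.join(d, f"{tag}.nwk")
        if os.path.exists(jpath) and os.path.exists(npath):
            continue
        entries = alrt_branch_support(res)
        _write_json(jpath, [
            {"node_id": e.node_id,
             "leaf_set": sorted(e.leaf_set),
             "aLRT": round(e.alrt, 10),
             "aLR": e.alr,
             "interpretation": f"{e.alr:.6g} times more likely than the "
                               "best topology lacking this branch"}
            for e in entries])
        with open(npath, "w") as fh:
            fh.write(write_newick(res.tree, with_support=True) + "\n")


def _stage_ancestors(config, outdir, ctx, cells):
    d = os.path.join(outdir, "ancestors")
    os.makedirs(d, exist_ok=True)
    ctx["ancestors"] = {}
    for (aln_name, spec), res in ctx["results"].items():
        tag = _cell_tag(aln_name, spec)
        rooted = root_by_outgroup(res.tree, config.outgroup)
        recon = marginal_posteriors(res, rooted_tree=rooted)
        ctx["ancestors"][(aln_name, spec)] = recon
        ctx["rooted"][(aln_name, spec)] = recon.tree
        fasta = os.path.join(d, f"{tag}.ml.fasta")
        if os.path.exists(fasta):
            continue
        lines = []
        sample_lines = []
        for nid in recon.node_ids():
            post = recon[nid]
            seq = ml_sequence(post)
            lines.append(f">Node{nid}|ML\n{seq.residues}")
            for j, s in enumerate(sample_sequences(
                    post, config.n_samples, seed=config.seed + nid)):
                sample_lines.append(f">Node{nid}|{s.kind}\n{s.residues}")
            _write_tsv(os.path.join(d, f"{tag}.Node{nid}.posteriors.tsv"),
                       recon.posterior_table(nid))
            summ = support_summary(post)
            _write_json(os.path.join(d, f"{tag}.Node{nid}.support.json"), {
                "node_id": nid,
                "bins": [round(b, 1) for b in summ.bin_edges.tolist()],
                "histogram": summ.histogram.tolist(),
                "n_non_indel_columns": int(summ.histogram.sum()),
            })
        with open(fasta, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        with open(os.path.join(d, f"{tag}.samples.fasta"), "w") as fh:
            fh.write("\n".join(sample_lines) + "\n")


def _stage_robustness(config, outdir, ctx, cells):
    d = os.path.join(outdir, "robustness")
    os.makedirs(d, exist_ok=True)
    grid = RobustnessGrid(trees=dict(ctx["rooted"]),
                          ancestors=dict(ctx.get("ancestors", {})))
    ctx["grid"] = grid
    rpath = os.path.join(d, "node_robustness.tsv")
    if len(grid.cells()) >= 2:
        report = robustness_report(grid)
        if not os.path.exists(rpath):
            _write_tsv(rpath, report)
            _write_json(os.path.join(d, "node_robustness.json"),
                        report.drop(columns=[]).to_dict(orient="records"))
    # per-branch candidate substitutions on the best cell of each alignment
    tpath = os.path.join(d, "branch_mutations.tsv")
    if os.path.exists(tpath):
        return
    rows = []
    for aln_name, aln in ctx["alignments"].items():
        best_cell = min(
            ((c, r) for c, r in ctx["results"].items() if c[0] == aln_name),
            key=lambda cr: (cr[1].aic, cr[0][1]))[0]
        recon = ctx["ancestors"][best_cell]
        tree = recon.tree
        for node in tree.base.postorder():
            if node.parent is None or node.parent.node_id not in recon.posteriors:
                continue
            parent_post = recon.posteriors[node.parent.node_id]
            if node.node_id in recon.posteriors:
                child_post = recon.posteriors[node.node_id]
            else:
                from .ancestral import leaf_posterior
                child_post = leaf_posterior(aln, node.name, node.node_id)
            from .robustness import diff_ancestors
            diff = diff_ancestors(parent_post, child_post,
                                  config.confident_threshold)
            for _, r in diff.table.iterrows():
                rows.append({
                    "alignment": aln_name, "model": best_cell[1],
                    "branch": f"Node{node.parent.node_id}->"
                              + (node.name if node.is_leaf
                                 else f"Node{node.node_id}"),
                    **r.to_dict()})
    _write_tsv(tpath, pd.DataFrame(
        rows, columns=["alignment", "model", "branch", "column",
                       "from_state", "from_support", "to_state",
                       "to_support", "class"]))


def product_hash(outdir: str) -> str:
    """SHA-256 over every product file (sorted paths); for determinism
    checks."""
    h = hashlib.sha256()
    for root, dirs, files in sorted(os.walk(outdir)):
        dirs.sort()
        for fn in sorted(files):
            if fn == "jobstate.json":
                continue
            path = os.path.join(root, fn)
            h.update(os.path.relpath(path, outdir).encode())
            with open(path, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()
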