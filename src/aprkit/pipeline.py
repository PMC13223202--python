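"""End-to-end orchestration.

One YAML config drives the full workflow: alignment in -> model
selection -> tree (+ bootstrap) -> marginal ancestral reconstruction
-> conservation / divergence tables -> ligand contacts and
protein-structure-network analysis for any supplied structures.  Every
stage writes a TSV (header on line 1, numerics at 10 significant
digits) into the report directory, and run.log records the config,
seed and per-stage timings.  Stages whose inputs are absent are
skipped with a logged notice; any stage error aborts the run.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, conservation, structnet
from .evomodel import AAModel, load_matrix
from .model import PhyloML
from .seqio import (
    Alignment, read_fasta, read_newick, read_pdb,
    read_phylip_interleaved, write_fasta, write_newick,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("aprkit")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StructureInput:
    path: str
    ligand: str | None = None
    chain: str | None = None
    sources: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    via: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    alignment: str
    tree: str | None = None
    seed: int = 0
    candidates: list[str] | None = None
    plus_gamma: bool = True
    plus_inv: bool = True
    plus_f: bool = False
    k: int = 4
    fixed_model: dict | None = None      # {"matrix":..., "alpha":..., "p_inv":...}
    nni: bool = True
    bootstrap: int = 500
    structures: list[StructureInput] = field(default_factory=list)
    clades: dict[str, list[str]] = field(default_factory=dict)
    conservation_queries: list[dict] = field(default_factory=list)
    divergence: dict | None = None       # {"a":..., "b":..., "reference":...}
    ancestor_nodes: list[int] = field(default_factory=list)
    ancestor_mrca: list[list[str]] = field(default_factory=list)
    ligand_cutoff: float = 4.0
    contact_cutoff: float = 6.0
    psn_cutoff: float = 3.0
    i_min: float = 0.0
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.bootstrap < 0:
            raise ValueError("bootstrap replicate count must be >= 0")
        for cut in (self.ligand_cutoff, self.contact_cutoff, self.psn_cutoff):
            if cut <= 0:
                raise ValueError("all distance cutoffs must be > 0")
        for p in [self.alignment, self.tree] + [s.path for s in self.structures]:
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"configured input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = raw.get("model", {})
        search = raw.get("search", {})
        sopts = raw.get("structure_options", {})
        anc = raw.get("ancestors", {})
        structures = [
            StructureInput(**entry) for entry in raw.get("structures", [])
        ]
        return cls(
            alignment=raw["alignment"],
            tree=raw.get("tree"),
            seed=int(raw.get("seed", 0)),
            candidates=model.get("candidates"),
            plus_gamma=bool(model.get("plus_gamma", True)),
            plus_inv=bool(model.get("plus_inv", True)),
            plus_f=bool(model.get("plus_f", False)),
            k=int(model.get("k", 4)),
            fixed_model=model.get("fixed"),
            nni=bool(search.get("nni", True)),
            bootstrap=int(search.get("bootstrap", 500)),
            structures=structures,
            clades=raw.get("clades", {}),
            conservation_queries=raw.get("conservation_queries", []),
            divergence=raw.get("divergence"),
            ancestor_nodes=list(anc.get("nodes", [])),
            ancestor_mrca=[list(x) for x in anc.get("mrca", [])],
            ligand_cutoff=float(sopts.get("ligand_cutoff", 4.0)),
            contact_cutoff=float(sopts.get("contact_cutoff", 6.0)),
            psn_cutoff=float(sopts.get("psn_cutoff", 3.0)),
            i_min=float(sopts.get("i_min", 0.0)),
            raw=raw,
        )


def _read_alignment(path: str) -> Alignment:
    if path.endswith((".phy", ".phylip")):
        return read_phylip_interleaved(path)
    return Alignment(read_fasta(path))


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> Path:
    """Run every configured stage and return the report directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.time()

    def stage(name):
        logger.info("stage %s: start", name)
        return time.time()

    def done(name, t0):
        logger.info("stage %s: done in %.2fs", name, time.time() - t0)

    try:
        logger.info("aprkit %s, seed %d", __version__, config.seed)
        logger.info("config: %r", config.raw or config)

        # ---- sequence stages ----------------------------------------
        name = "load"
        t0 = stage(name)
        try:
            aln = _read_alignment(config.alignment).drop_all_gap_columns()
            tree0 = read_newick(config.tree) if config.tree else None
        except Exception as e:
            raise PipelineError(name, e)
        done(name, t0)

        name = "model+tree"
        t0 = stage(name)
        try:
            fixed = None
            if config.fixed_model:
                fm = dict(config.fixed_model)
                S, pi = load_matrix(fm.pop("matrix", "LG"))
                fixed = AAModel(fm.pop("name", "fixed"), S, pi, **fm)
            ml = PhyloML(
                aln, tree=tree0, substitution_model=fixed,
                candidates=config.candidates, plus_gamma=config.plus_gamma,
                plus_inv=config.plus_inv, plus_f=config.plus_f, k=config.k,
            )
            fit = ml.fit(nni=config.nni, bootstrap=config.bootstrap,
                         seed=config.seed)
            if fit.selection_table is not None:
                _write_tsv(fit.selection_table, out / "model_selection.tsv")
            write_newick(fit.tree, out / "tree.nwk")
            with open(out / "summary.txt", "w") as fh:
                fh.write(fit.summary() + "\n")
            logger.info("model %s lnL %.6f", fit.substitution_model.label, fit.llf)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(name, e)
        done(name, t0)

        name = "ancestral"
        t0 = stage(name)
        try:
            anc = fit.ancestral()
            seqs = []
            rows = []
            for nid, (seq, mean_pp) in sorted(anc.map_sequences().items()):
                seqs.append(seq)
                rows.append({"node": nid, "mean_pp": mean_pp})
            write_fasta(seqs, out / "ancestors.fasta")
            _write_tsv(anc.posterior_table(), out / "posteriors.tsv")
            node_table = anc.node_table()
            import pandas as pd

            node_table = node_table.merge(pd.DataFrame(rows), on="node")
            for nid in config.ancestor_nodes:
                anc.labeling.node(nid)  # raises on unknown id
            for tips in config.ancestor_mrca:
                nid = anc.mrca(tips)
                logger.info("MRCA of %s = node %d", tips, nid)
            _write_tsv(node_table, out / "node_table.tsv")
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(name, e)
        done(name, t0)

        name = "conservation"
        t0 = stage(name)
        try:
            ident = conservation.identity_matrix(aln)
            ident.insert(0, "id", ident.index)
            _write_tsv(ident, out / "identity.tsv")
            _write_tsv(conservation.conservation_profile(aln), out / "conservation.tsv")
            rows = []
            for q in config.conservation_queries:
                pct = conservation.clade_conservation(
                    aln, config.clades[q["clade"]], q["reference"], int(q["position"]),
                )
                rows.append({"clade": q["clade"], "reference": q["reference"],
                             "position": q["position"], "conserved_pct": pct})
            if rows:
                import pandas as pd

                _write_tsv(pd.DataFrame(rows), out / "clade_conservation.tsv")
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(name, e)
        done(name, t0)

        if config.divergence:
            name = "divergence"
            t0 = stage(name)
            try:
                dv = conservation.divergent_positions(
                    aln, config.divergence["a"], config.divergence["b"],
                    config.divergence.get("reference"),
                )
                _write_tsv(dv, out / "divergence.tsv")
            except Exception as e:
                raise PipelineError(name, e)
            done(name, t0)
        else:
            logger.info("stage divergence: skipped (not configured)")

        # ---- structure stages ---------------------------------------
        if config.structures:
            name = "structures"
            t0 = stage(name)
            try:
                import pandas as pd

                contact_frames, edge_frames, path_frames = [], [], []
                for sin in config.structures:
                    st = read_pdb(sin.path)
                    tag = os.path.basename(sin.path)
                    if sin.ligand:
                        cs = structnet.ligand_contacts(
                            st, sin.ligand, config.ligand_cutoff
                        )
                        f = cs.to_frame()
                        f.insert(0, "structure", tag)
                        f.insert(1, "ligand", sin.ligand)
                        contact_frames.append(f)
                    G = structnet.build_psn(
                        st, config.psn_cutoff, config.i_min, chain=sin.chain
                    )
                    ef = pd.DataFrame(
                        [(a, b, d["n_pairs"], d["strength"])
                         for a, b, d in sorted(G.edges(data=True))],
                        columns=["res_i", "res_j", "n_pairs", "strength"],
                    )
                    ef.insert(0, "structure", tag)
                    edge_frames.append(ef)
                    if sin.sources and sin.targets:
                        ps = structnet.communication_paths(
                            G, sin.sources, sin.targets, via=sin.via or None
                        )
                        pf = ps.to_frame()
                        pf.insert(0, "structure", tag)
                        path_frames.append(pf)
                        logger.info(
                            "%s: %d paths reach %s", tag, len(ps),
                            structnet.reached_targets(ps, sin.targets),
                        )
                if contact_frames:
                    _write_tsv(pd.concat(contact_frames), out / "contacts.tsv")
                if edge_frames:
                    _write_tsv(pd.concat(edge_frames), out / "psn_edges.tsv")
                if path_frames:
                    _write_tsv(pd.concat(path_frames), out / "psn_paths.tsv")
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e)
            done(name, t0)
        else:
            logger.info("stage structures: skipped (no structures configured)")

        logger.info("pipeline complete in %.2fs", time.time() - t_start)
        return out
    except PipelineError as e:
        logger.error("%s", e)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
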