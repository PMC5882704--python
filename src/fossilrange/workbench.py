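"""Config-driven orchestration: model grids, comparison tables, bundles.

`run_config` reproduces the full study structure from one configuration:
time-scale (or accept) a tree, fit a grid of range-evolution models,
compare them (LRT within families, AICc across), reconstruct ancestral
ranges, run stochastic mapping for the selected models, and compute
diversification shifts and diversity curves.  All outputs are CSV/Newick/
JSON files in the bundle directory.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .data import AgeTable, parse_ages, parse_geography
from .diversification import (TimeBin, detect_shifts, diversity_curves,
                              flag_artefacts, validate_bins)
from .likelihood import RangeEvolutionModel, RangeEvolutionResults, lrt
from .model import ModelSpec, Stratum
from .trees import TimeTree, parse_tree, timescale_equal, write_tree

__all__ = ["RunConfig", "load_config", "run_config", "model_table",
           "timetree_from_lengths"]


_TIERS = ("M0", "M1", "M2")


@dataclass
class RunConfig:
    tree_path: str
    ages_path: str
    geography_path: str
    outdir: str
    stratum_bounds: list[float]            # e.g. [170, 91.1, 55.5, 0]
    distance_paths: list[str] = field(default_factory=list)
    bin_names: list[str] = field(default_factory=list)
    bin_bounds: list[float] = field(default_factory=list)
    model_grid: list[str] = field(default_factory=lambda: ["DEC:M0"])
    max_range_size: int | None = None
    root_extension: float = 10.0
    timescale: bool = True
    prune: list[str] = field(default_factory=list)
    n_maps: int = 50
    n_starts: int = 5
    seed: int = 1
    alpha: float = 0.05
    n_null: int = 1999

    def __post_init__(self):
        if not self.model_grid:
            raise ValueError("model grid is empty")
        for path in (self.tree_path, self.ages_path, self.geography_path,
                     *self.distance_paths):
            if path and not Path(path).exists():
                raise FileNotFoundError(path)


def load_config(path) -> RunConfig:
    """Read the flat key/value + sections run configuration (INI)."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    base = Path(path).parent

    def _path(section, key, default=None):
        raw = cp.get(section, key, fallback=default)
        if raw in (None, ""):
            return raw
        p = Path(raw)
        return str(p if p.is_absolute() else base / p)

    def _list(section, key, default=""):
        raw = cp.get(section, key, fallback=default)
        return [s.strip() for s in raw.split(",") if s.strip()]

    dist = []
    for d in _list("strata", "distances"):
        p = Path(d)
        dist.append(str(p if p.is_absolute() else base / p))
    return RunConfig(
        tree_path=_path("data", "tree"),
        ages_path=_path("data", "ages"),
        geography_path=_path("data", "geography"),
        outdir=_path("run", "outdir", str(base / "bundle")),
        stratum_bounds=[float(x) for x in _list("strata", "bounds")],
        distance_paths=dist,
        bin_names=_list("bins", "names"),
        bin_bounds=[float(x) for x in _list("bins", "bounds")],
        model_grid=_list("models", "grid", "DEC:M0"),
        max_range_size=cp.getint("models", "m", fallback=0) or None,
        root_extension=cp.getfloat("run", "root_extension", fallback=10.0),
        timescale=cp.getboolean("run", "timescale", fallback=True),
        prune=_list("run", "prune"),
        n_maps=cp.getint("run", "n_maps", fallback=50),
        n_starts=cp.getint("run", "n_starts", fallback=5),
        seed=cp.getint("run", "seed", fallback=1),
        alpha=cp.getfloat("run", "alpha", fallback=0.05),
        n_null=cp.getint("run", "n_null", fallback=1999),
    )


def timetree_from_lengths(newick: str, ages: AgeTable,
                          tol: float = 1e-6) -> TimeTree:
    """Interpret a Newick string with branch lengths as a pre-scaled tree.

    Leaf ages are the FADs; the root age implied by each leaf (FAD + path
    length to the root) must agree within ``tol``.
    """
    import dendropy
    from .trees import Node, TreeError

    dtree = dendropy.Tree.get(data=newick, schema="newick")
    root_ages = []
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        if label not in ages.fad:
            raise TreeError(f"leaf {label} missing from the age table")
        depth = 0.0
        n = leaf
        while n.parent_node is not None:
            depth += n.edge.length or 0.0
            n = n.parent_node
        root_ages.append(ages.fad[label] + depth)
    root_age = root_ages[0]
    if max(root_ages) - min(root_ages) > tol:
        raise TreeError("branch lengths and FADs imply inconsistent root "
                        "ages; re-run with timescale=true")

    def convert(dnode, age):
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        node = Node(label=label, age=age)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild, age - (dchild.edge.length or 0.0)))
        return node

    return TimeTree(convert(dtree.seed_node, root_age))


def _parse_spec(token: str, m: int | None) -> ModelSpec:
    try:
        family, tier = token.split(":")
    except ValueError:
        raise ValueError(f"model grid entry {token!r}; expected FAMILY:TIER")
    return ModelSpec(family=family.strip().upper(), tier=tier.strip().upper(),
                     max_range_size=m)


def build_strata(bounds: Sequence[float],
                 distance_paths: Sequence[str]) -> list[Stratum]:
    if len(bounds) < 2:
        raise ValueError("need at least two stratum bounds")
    mats = [pd.read_csv(p, index_col=0).to_numpy(dtype=float)
            for p in distance_paths]
    if mats and len(mats) != len(bounds) - 1:
        raise ValueError("one distance matrix per stratum required")
    out = []
    for i, (older, younger) in enumerate(zip(bounds, bounds[1:])):
        out.append(Stratum(older, younger, mats[i] if mats else None))
    return out


def build_bins(names: Sequence[str], bounds: Sequence[float]) -> list[TimeBin]:
    if len(bounds) != len(names) + 1:
        raise ValueError("bin bounds must be one longer than bin names")
    return validate_bins([TimeBin(n, o, y) for n, o, y in
                          zip(names, bounds, bounds[1:])])


# ---------------------------------------------------------------------------
# Model comparison table
# ---------------------------------------------------------------------------

def model_table(fits: Sequence[RangeEvolutionResults],
                nesting: dict[str, str] | None = None) -> pd.DataFrame:
    """Comparison table: LnL, df, LRT p against the declared null, AICc,
    delta-AICc and Akaike weights; the best model carries delta_aicc 0.

    ``nesting`` maps a model name to its null model's name (default: M1 is
    tested against M0 and M2 against M1 within each family).
    """
    if not fits:
        raise ValueError("no fits")
    by_name = {f.spec.name: f for f in fits}
    if nesting is None:
        nesting = {}
        for f in fits:
            fam, tier = f.spec.family, f.spec.tier
            if tier != "M0":
                null = f"{fam}-{_TIERS[_TIERS.index(tier) - 1]}"
                if null in by_name:
                    nesting[f.spec.name] = null
    else:
        for alt, null in nesting.items():
            if alt not in by_name or null not in by_name:
                raise KeyError(f"nesting refers to absent fit {alt}/{null}")

    rows = []
    aiccs = np.array([f.aicc for f in fits])
    best = aiccs.min()
    rel = np.exp(-0.5 * (aiccs - best))
    weights = rel / rel.sum()
    for f, w in zip(fits, weights):
        name = f.spec.name
        row = {
            "model": name, "LnL": f.llf, "df": f.k,
            "null_model": "", "LRT_G": np.nan, "LRT_p": np.nan,
            "AICc": f.aicc, "delta_AICc": f.aicc - best,
            "AICc_weight": w,
            "d": f.params.d, "e": f.params.e,
            "x": f.params.x if f.spec.x_free else np.nan,
            "j": f.params.j if f.spec.j_free else np.nan,
            "converged": f.converged,
        }
        if name in nesting:
            null_fit = by_name[nesting[name]]
            G, df, p = lrt(null_fit, f)
            row.update(null_model=nesting[name], LRT_G=G, LRT_p=p)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    table["best"] = table["delta_AICc"] == 0.0
    return table


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_config(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; returns a manifest of written artifacts.

    Stages: read inputs -> time-scale -> prune -> fit model grid ->
    comparison table -> ancestral marginals -> BSM for the AICc-best model
    -> diversification shifts -> diversity curves.  Any stage failure
    raises with the stage name; artifacts written so far are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stage = "read-inputs"
    try:
        clad = parse_tree(Path(cfg.tree_path).read_text())
        ages = parse_ages(Path(cfg.ages_path).read_text())
        geo = parse_geography(Path(cfg.geography_path).read_text())
        strata = build_strata(cfg.stratum_bounds, cfg.distance_paths)

        stage = "timescale"
        if cfg.timescale:
            tree = timescale_equal(clad, ages, cfg.root_extension)
        else:
            tree = timetree_from_lengths(Path(cfg.tree_path).read_text(),
                                         ages)
        if cfg.prune:
            from .trees import prune_taxa
            tree = prune_taxa(tree, cfg.prune)
            geo = geo.subset(tree.leaf_labels)
        (outdir / "timetree.nwk").write_text(write_tree(tree))
        manifest["timetree"] = "timetree.nwk"

        stage = "fit-models"
        fits = []
        for gi, token in enumerate(cfg.model_grid):
            spec = _parse_spec(token, cfg.max_range_size)
            model = RangeEvolutionModel(tree, geo, spec, strata)
            # namespaced seed per grid entry for reproducible partial reruns
            fits.append(model.fit(n_starts=cfg.n_starts,
                                  seed=cfg.seed * 1000 + gi))

        stage = "model-table"
        table = model_table(fits)
        table.to_csv(outdir / "model_comparison.csv", index=False)
        manifest["model_comparison"] = "model_comparison.csv"

        stage = "ancestral-ranges"
        for f in fits:
            marg = f.ancestral_marginals()
            name = f.spec.name.replace("-", "_")
            marg.to_csv(outdir / f"ancestral_{name}.csv", index=False)
            manifest[f"ancestral_{name}"] = f"ancestral_{name}.csv"
            (outdir / f"ancestral_{name}.nwk").write_text(f.annotated_tree())
            manifest[f"ancestral_{name}_tree"] = f"ancestral_{name}.nwk"

        stage = "bsm"
        best_name = table.loc[table["best"], "model"].iloc[0]
        best_fit = next(f for f in fits if f.spec.name == best_name)
        bsm_table = best_fit.summarize_bsm(n_maps=cfg.n_maps,
                                           seed=cfg.seed * 1000 + 500)
        bsm_table.to_csv(outdir / "bsm_summary.csv", index=False)
        manifest["bsm_summary"] = "bsm_summary.csv"

        stage = "shifts"
        if cfg.bin_names:
            bins = build_bins(cfg.bin_names, cfg.bin_bounds)
            report = detect_shifts(tree, bins, alpha=cfg.alpha,
                                   n_null=cfg.n_null,
                                   seed=cfg.seed * 1000 + 900, ages=ages)
            report = flag_artefacts(report, tree, ages, bins)
            report.frame.to_csv(outdir / "shifts.csv", index=False)
            manifest["shifts"] = "shifts.csv"

            stage = "curves"
            curves = diversity_curves(tree, ages, bins)
            curves.to_csv(outdir / "diversity_curves.csv", index=False)
            manifest["diversity_curves"] = "diversity_curves.csv"

        stage = "log"
        log = {
            "version": __version__, "seed": cfg.seed,
            "model_grid": cfg.model_grid, "n_maps": cfg.n_maps,
            "n_starts": cfg.n_starts, "best_model": best_name,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
        manifest["run_log"] = "run_log.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return manifest
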