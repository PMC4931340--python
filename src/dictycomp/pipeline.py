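"""End-to-end orchestration: simulate → homology → trees → orthology →
LGT → expression → enrichment → summaries.

Every stage reads and writes plain TSV/JSON in a run directory so the
stages are independently invokable (see :mod:`dictycomp.cli`), and a
run manifest records parameters, seed and input checksums.  Outputs
are deterministic for a fixed config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import expression as expr
from .gene_trees import (
    alignment_distances,
    bootstrap_support,
    implied_alignment,
    midpoint_root,
    neighbor_joining,
)
from .homology import blosum62_matrix, find_bbh, local_align_score
from .io_formats import (
    DICTYOSTELIDS,
    SPECIES_CODES,
    read_annotations,
    read_fasta,
    read_newick,
    read_species_map,
    write_newick,
)
from .lgt import LGTEvidence, lgt_verdict, prokaryote_sister_test, screen_candidates
from .orthology import (
    ConservationProfile,
    classify_homologs,
    compare_architecture,
    conservation_category,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    data_dir: Path
    out_dir: Path
    min_score: float = 40.0
    support_min: float = 0.7
    branch_length_factor: float = 3.0
    theta: float = 0.25
    bootstrap_reps: int = 50
    seed: int = 0

    def __post_init__(self):
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)


@dataclass
class Bundle:
    """In-memory view of a dataset directory."""

    records: dict  # id -> ProteinRecord (annotated)
    species_map: dict
    families: dict  # family id -> sorted list of member gene ids
    expression: pd.DataFrame | None
    species_tree: object


def load_bundle(data_dir: str | Path) -> Bundle:
    data_dir = Path(data_dir)
    tree_path = data_dir / "species_tree.nwk"
    if not tree_path.exists():
        raise FileNotFoundError(
            f"missing species tree: expected '{tree_path}' (field species_tree)")
    species_tree = read_newick(tree_path.read_text(), rooted=True)
    records = []
    for fa in sorted(data_dir.glob("*.fasta")):
        records.extend(read_fasta(fa))
    ann = data_dir / "annotations.tsv"
    if ann.exists():
        read_annotations(ann, records)
    species_map = read_species_map(data_dir / "species_map.tsv")
    for rec in records:
        rec.species = species_map.get(rec.id, rec.species)
    families: dict[str, list] = {}
    fam_path = data_dir / "families.tsv"
    if fam_path.exists():
        with open(fam_path) as fh:
            for line in fh:
                gid, fid = line.rstrip("\n").split("\t")
                families.setdefault(fid, []).append(gid)
        families = {f: sorted(g) for f, g in families.items()}
    expr_path = data_dir / "expression.tsv"
    expression = pd.read_csv(expr_path, sep="\t") if expr_path.exists() else None
    return Bundle({r.id: r for r in records}, species_map, families,
                  expression, species_tree)


def _amoebozoan(bundle, fid):
    return [g for g in bundle.families[fid]
            if bundle.records[g].species in SPECIES_CODES]


def _outgroup(bundle, fid):
    return [g for g in bundle.families[fid]
            if bundle.records[g].species not in SPECIES_CODES]


def _family_seed(seed: int, fid: str) -> int:
    h = hashlib.sha256(f"{seed}:{fid}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stages


def stage_bbh(bundle: Bundle, cfg: RunConfig) -> dict:
    """Within-family BBH pairs (DD vs each species) and best outgroup hits."""
    matrix = blosum62_matrix()
    bbh_rows = []
    outgroup_rows = []
    for fid in sorted(bundle.families):
        amoeb = [bundle.records[g] for g in _amoebozoan(bundle, fid)]
        og = [bundle.records[g] for g in _outgroup(bundle, fid)]
        dd = [r for r in amoeb if r.species == "DD"]
        if dd:
            for sp in SPECIES_CODES:
                if sp == "DD":
                    continue
                others = [r for r in amoeb if r.species == sp]
                if not others:
                    continue
                for pair in sorted(find_bbh(dd, others, min_score=cfg.min_score,
                                            matrix=matrix),
                                   key=lambda p: (p.gene_a, p.gene_b)):
                    bbh_rows.append({"family": fid, "species": sp,
                                     "gene_dd": pair.gene_a, "gene_other": pair.gene_b})
        if og and amoeb:
            # closest homolog outside Amoebozoa, per focal DD gene
            for focal in sorted(dd, key=lambda r: r.id):
                best, best_score = None, -1.0
                for cand in sorted(og, key=lambda r: r.id):
                    score, _ = local_align_score(focal.sequence, cand.sequence,
                                                 matrix=matrix)
                    if score > best_score:
                        best, best_score = cand, score
                if best is None or best_score < cfg.min_score:
                    continue
                reverse_in_lineage = False
                if best.kingdom == "prokaryote":
                    # does the prokaryote's best eukaryote hit fall in this lineage?
                    rb, rb_score = None, -1.0
                    euks = [r for r in amoeb] + [r for r in og
                                                 if r.kingdom != "prokaryote"]
                    for cand in sorted(euks, key=lambda r: r.id):
                        score, _ = local_align_score(best.sequence, cand.sequence,
                                                     matrix=matrix)
                        if score > rb_score:
                            rb, rb_score = cand, score
                    reverse_in_lineage = rb is not None and rb.species in SPECIES_CODES
                outgroup_rows.append({
                    "family": fid, "focal": focal.id, "best_outgroup": best.id,
                    "kingdom": best.kingdom, "score": best_score,
                    "bbh_prokaryote": reverse_in_lineage})
    out = {"bbh": bbh_rows, "outgroup_hits": outgroup_rows}
    _write_tsv(cfg.out_dir / "bbh.tsv", bbh_rows,
               ["family", "species", "gene_dd", "gene_other"])
    _write_tsv(cfg.out_dir / "outgroup_hits.tsv", outgroup_rows,
               ["family", "focal", "best_outgroup", "kingdom", "score",
                "bbh_prokaryote"])
    return out


def stage_trees(bundle: Bundle, cfg: RunConfig) -> dict:
    """Bootstrap-supported, midpoint-rooted NJ tree per family."""
    trees = {}
    for fid in sorted(bundle.families):
        genes = _amoebozoan(bundle, fid)
        if len(genes) < 3:
            continue
        recs = [bundle.records[g] for g in genes]
        tree = bootstrap_support(recs, n_reps=cfg.bootstrap_reps,
                                 seed=_family_seed(cfg.seed, fid))
        trees[fid] = tree
    with open(cfg.out_dir / "trees.tsv", "w") as fh:
        fh.write("family\tnewick\n")
        for fid in sorted(trees):
            fh.write(f"{fid}\t{write_newick(trees[fid]).strip()}\n")
    return trees


def stage_expression(bundle: Bundle, cfg: RunConfig) -> dict:
    """Percent-of-max profiles per species and divergence calls per family."""
    if bundle.expression is None:
        raise FileNotFoundError("no expression.tsv in the data directory")
    df = bundle.expression
    gene_family = {g: fid for fid, genes in bundle.families.items() for g in genes}
    profiles: dict[str, dict[str, list]] = {}
    profile_rows = []
    df = df.sort_values(["gene", "stage_index"])
    for (gene, species), grp in df.groupby(["gene", "species"], sort=True):
        series = expr.build_series(
            gene, species, grp["raw"].tolist(), grp["total_reads"].tolist(),
            grp["avg_read_length"].tolist(), stages=tuple(grp["stage"]))
        fid = gene_family.get(gene)
        if fid is None:
            continue
        profiles.setdefault(fid, {}).setdefault(species, []).append(series)
        for stage, pct in zip(series.stages, series.percent_of_max):
            profile_rows.append({"family": fid, "gene": gene, "species": species,
                                 "stage": stage, "percent_of_max": round(pct, 4)})
    results = {}
    div_rows = []
    for fid in sorted(profiles):
        per_species = {}
        for sp, series_list in profiles[fid].items():
            norm = np.mean([s.normalized for s in series_list], axis=0)
            pct, _ = expr.percent_of_max(list(norm))
            per_species[sp] = pct
        if len(per_species) < 3:
            # too few species to apply the two-other-species criterion:
            # no evidence of divergence
            res = expr.DivergenceResult(
                gene=fid, flags=tuple((sp, False) for sp in sorted(per_species)),
                pattern="conserved", theta=cfg.theta)
        else:
            res = expr.call_divergence(per_species, theta=cfg.theta, gene=fid)
        results[fid] = res
        div_rows.append({"family": fid, "pattern": res.pattern,
                         "divergent_species": ",".join(res.divergent_species),
                         "theta": cfg.theta})
    _write_tsv(cfg.out_dir / "profiles.tsv", profile_rows,
               ["family", "gene", "species", "stage", "percent_of_max"])
    _write_tsv(cfg.out_dir / "divergence.tsv", div_rows,
               ["family", "pattern", "divergent_species", "theta"])
    return results


def stage_classify(bundle: Bundle, cfg: RunConfig, trees: dict,
                   divergence: dict | None = None) -> dict:
    """Orthology calls and conservation profiles per focal DD gene."""
    divergence = divergence or {}
    profiles = {}
    call_rows = []
    cat_rows = []
    for fid in sorted(bundle.families):
        genes = _amoebozoan(bundle, fid)
        dd_genes = [g for g in genes if bundle.records[g].species == "DD"]
        if not dd_genes:
            continue
        present_by_sp: dict[str, list] = {}
        for g in genes:
            present_by_sp.setdefault(bundle.records[g].species, []).append(g)
        div = divergence.get(fid)
        div_flags = dict(div.flags) if div is not None else {}
        for focal in sorted(dd_genes):
            if fid in trees:
                calls = classify_homologs(
                    focal, trees[fid], bundle.species_tree, bundle.species_map,
                    support_min=cfg.support_min,
                    branch_length_factor=cfg.branch_length_factor)
            else:
                # too few genes for a tree: single-copy presence logic
                calls = {}
                from .orthology import OrthologyCall
                for sp in SPECIES_CODES:
                    members = sorted(present_by_sp.get(sp, []))
                    if sp == "DD":
                        calls[sp] = OrthologyCall(focal, sp, focal, "ortholog")
                    elif not members:
                        calls[sp] = OrthologyCall(focal, sp, None, "absent")
                    elif len(members) == 1:
                        calls[sp] = OrthologyCall(focal, sp, members[0], "ortholog")
                    else:
                        calls[sp] = OrthologyCall(focal, sp, members[0],
                                                  "homolog_unresolved")
            prof = ConservationProfile(focal=focal, calls=calls)
            focal_rec = bundle.records[focal]
            for sp, call in calls.items():
                if call.gene and call.gene != focal:
                    prof.domain_conserved[sp] = compare_architecture(
                        focal_rec.architecture, bundle.records[call.gene].architecture)
                prof.expression_divergent[sp] = bool(div_flags.get(sp, False))
            prof.category = conservation_category(
                {sp: c.call for sp, c in calls.items()})
            profiles[focal] = prof
            for sp in SPECIES_CODES:
                c = calls[sp]
                call_rows.append({
                    "focal": focal, "family": fid, "species": sp,
                    "gene": c.gene or "-", "call": c.call,
                    "branch_length_flag": c.branch_length_flag,
                    "domain_conserved": prof.domain_conserved.get(sp, ""),
                    "expression_divergent": prof.expression_divergent.get(sp, "")})
            cat = prof.category
            cat_rows.append({
                "focal": focal, "family": fid, "category": cat.category,
                "only": cat.only or "-", "all5_ortholog": cat.all5_ortholog,
                "multi_only": cat.multi_only, "uni_plus_multi": cat.uni_plus_multi})
    _write_tsv(cfg.out_dir / "orthology_calls.tsv", call_rows,
               ["focal", "family", "species", "gene", "call",
                "branch_length_flag", "domain_conserved", "expression_divergent"])
    _write_tsv(cfg.out_dir / "conservation_categories.tsv", cat_rows,
               ["focal", "family", "category", "only", "all5_ortholog",
                "multi_only", "uni_plus_multi"])
    return profiles


def stage_lgt(bundle: Bundle, cfg: RunConfig, profiles: dict,
              outgroup_hits: list) -> list:
    """Screen LGT candidates and run the two-criterion validation."""
    hit_by_focal = {row["focal"]: row for row in outgroup_hits}
    presence = {focal: {sp: c.call for sp, c in prof.calls.items()}
                for focal, prof in profiles.items()}
    kingdom_of = {focal: row["kingdom"] for focal, row in hit_by_focal.items()}
    candidates = screen_candidates(presence, kingdom_of)
    gene_family = {g: fid for fid, genes in bundle.families.items() for g in genes}
    rows = []
    verdicts = []
    done_families = set()
    for focal in candidates:
        fid = gene_family[focal]
        if fid in done_families:
            continue
        done_families.add(fid)
        amoeb = _amoebozoan(bundle, fid)
        og = _outgroup(bundle, fid)
        # tree over the focal-species genes plus the closest prokaryote and
        # eukaryote homologs (not the whole dictyostelid subfamily, whose
        # internal depth would swamp the sister signal)
        dd_ids = [g for g in amoeb if bundle.records[g].species == "DD"]
        all_ids = dd_ids + og
        if len(all_ids) < 3 or not dd_ids:
            continue
        recs = [bundle.records[g] for g in sorted(all_ids)]
        ids, mat = implied_alignment([(r.id, r.sequence) for r in recs])
        tree1 = midpoint_root(neighbor_joining(
            alignment_distances(ids, mat, poisson=True)))
        tree2 = midpoint_root(neighbor_joining(
            alignment_distances(ids, mat, poisson=False)))
        kingdom_map = {r.id: r.kingdom for r in recs}
        lineage = set(dd_ids)
        try:
            m1 = prokaryote_sister_test(tree1, lineage, kingdom_map)
            m2 = prokaryote_sister_test(tree2, lineage, kingdom_map)
        except ValueError:
            m1 = m2 = False
        species_present = {bundle.records[g].species for g in amoeb}
        transcribed = True
        if bundle.expression is not None:
            fam_expr = bundle.expression[bundle.expression["gene"].isin(amoeb)]
            transcribed = bool((fam_expr["raw"] > 0).any()) if len(fam_expr) else False
        ev = LGTEvidence(
            gene_id=focal,
            bbh_prokaryote=bool(hit_by_focal[focal]["bbh_prokaryote"]),
            sister_prok_method1=m1,
            sister_prok_method2=m2,
            present_all_dicty=set(DICTYOSTELIDS) <= species_present,
            transcribed=transcribed)
        v = lgt_verdict(ev)
        verdicts.append(v)
        rows.append({"family": fid, "focal": focal,
                     "bbh_prokaryote": ev.bbh_prokaryote,
                     "sister_prok_method1": m1, "sister_prok_method2": m2,
                     "present_all_dicty": ev.present_all_dicty,
                     "transcribed": ev.transcribed,
                     "verdict": v.verdict, "note": v.note or "-"})
    _write_tsv(cfg.out_dir / "lgt_verdicts.tsv", rows,
               ["family", "focal", "bbh_prokaryote", "sister_prok_method1",
                "sister_prok_method2", "present_all_dicty", "transcribed",
                "verdict", "note"])
    return verdicts


def stage_enrich(bundle: Bundle, cfg: RunConfig, profiles: dict) -> dict:
    """GO enrichment and membrane classes for multi-only vs uni+multi sets."""
    focals = sorted(profiles)
    genome = [bundle.records[f] for f in focals]
    multi_only = [f for f in focals if profiles[f].category.multi_only]
    uni_multi = [f for f in focals if profiles[f].category.uni_plus_multi]
    enrich_rows = []
    membrane = {}
    for set_name, genes in (("multi_only", multi_only), ("uni_plus_multi", uni_multi)):
        if genes:
            for row in enr.go_enrichment(genes, genome):
                enrich_rows.append({
                    "set": set_name, "term": row.term, "set_count": row.set_count,
                    "set_size": row.set_size, "genome_count": row.genome_count,
                    "genome_size": row.genome_size,
                    "factor": round(row.factor, 6),
                    "pvalue": f"{row.pvalue:.6g}",
                    "adjusted_pvalue": f"{row.adjusted_pvalue:.6g}"})
        _, summary = enr.membrane_classify([bundle.records[g] for g in genes])
        membrane[set_name] = summary
    _write_tsv(cfg.out_dir / "enrichment.tsv", enrich_rows,
               ["set", "term", "set_count", "set_size", "genome_count",
                "genome_size", "factor", "pvalue", "adjusted_pvalue"])
    with open(cfg.out_dir / "membrane.json", "w") as fh:
        json.dump(membrane, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"enrichment": enrich_rows, "membrane": membrane}


DEFAULT_DOMAIN_PAIRS = (("Dicty_CTDC", "PA14"), ("Spore_N", "FOLN"), ("TIG", "EGF"))


def stage_summarize(bundle: Bundle, cfg: RunConfig, profiles: dict,
                    divergence: dict, verdicts: list) -> dict:
    """Conservation, divergence-pattern and domain-family summaries."""
    prof_list = [profiles[f] for f in sorted(profiles)]
    conserve = enr.conservation_percentages(prof_list)
    div_counts = enr.divergence_distribution(
        [divergence[f] for f in sorted(divergence)])
    amoeb_records = [r for r in bundle.records.values()
                     if r.species in SPECIES_CODES]
    fam_counts = enr.family_counts(amoeb_records, DEFAULT_DOMAIN_PAIRS)
    limited = enr.limited_conservation_table(
        prof_list, [bundle.records[f] for f in sorted(profiles)])
    lgt_counts = {}
    for v in verdicts:
        lgt_counts[v.verdict] = lgt_counts.get(v.verdict, 0) + 1
    matrix_rows = []
    for prof in prof_list:
        row = {"focal": prof.focal}
        for sp in SPECIES_CODES:
            c = prof.calls.get(sp)
            letter = {"ortholog": "O", "paralog": "P",
                      "homolog_unresolved": "H", "absent": "-"}[c.call if c else "absent"]
            if c and c.gene and prof.domain_conserved.get(sp) is False:
                letter += "d"
            if prof.expression_divergent.get(sp):
                letter += "x"
            row[sp] = letter
        matrix_rows.append(row)
    _write_tsv(cfg.out_dir / "fig2_matrix.tsv", matrix_rows,
               ["focal"] + list(SPECIES_CODES))
    summary = {
        "conservation": conserve,
        "divergence_patterns": div_counts,
        "lgt_verdict_counts": lgt_counts,
        "limited_conservation": {k: v for k, v in limited.items() if k != "rows"},
        "family_counts": {f"{a}/{b}": v for (a, b), v in fam_counts.items()},
    }
    with open(cfg.out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------


def _write_tsv(path, rows, columns):
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def _input_checksums(data_dir: Path) -> dict:
    out = {}
    for path in sorted(Path(data_dir).iterdir()):
        if path.is_file():
            out[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and emit the report bundle plus a run manifest."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(cfg.data_dir)
    homology_out = stage_bbh(bundle, cfg)
    trees = stage_trees(bundle, cfg)
    divergence = stage_expression(bundle, cfg) if bundle.expression is not None else {}
    profiles = stage_classify(bundle, cfg, trees, divergence)
    verdicts = stage_lgt(bundle, cfg, profiles, homology_out["outgroup_hits"])
    enrich_out = stage_enrich(bundle, cfg, profiles)
    summary = stage_summarize(bundle, cfg, profiles, divergence, verdicts)
    manifest = {
        "parameters": {
            "min_score": cfg.min_score, "support_min": cfg.support_min,
            "branch_length_factor": cfg.branch_length_factor,
            "theta": cfg.theta, "bootstrap_reps": cfg.bootstrap_reps,
            "seed": cfg.seed},
        "data_dir": str(cfg.data_dir),
        "input_checksums": _input_checksums(cfg.data_dir),
    }
    with open(cfg.out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "profiles": profiles, "divergence": divergence, "verdicts": verdicts,
        "summary": summary, "enrichment": enrich_out, "trees": trees,
    }
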