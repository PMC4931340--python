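"""Gene-family evolution simulator with known ground truth.

Families evolve along a fixed eight-species amoebozoan tree (five
dictyostelids: DD, DP, DL, PP, DF; three unicellular relatives: PhyP,
AC, EH) by a birth–death process (duplication/loss), with optional
prokaryote-to-Dictyostelia transfers, protein sequences under a
Jukes–Cantor-style substitution process, seven-stage developmental
expression profiles with clade-specific divergence events, and
token-list domain architectures with per-branch gain/loss.  Every event
is logged so downstream orthology, LGT and expression-divergence calls
can be scored against the truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    DICTYOSTELIDS,
    ProteinRecord,
    read_newick,
    write_fasta,
)

log = logging.getLogger(__name__)

#: The seven canonical developmental stages, in order.
STAGES = (
    "growth",
    "early_aggregation",
    "late_aggregation",
    "tipped_mound",
    "slug",
    "early_culmination",
    "fruiting_body",
)

#: Fixed species topology; 0.3 substitutions/site per branch, 0.6 on the
#: long stems of the unicellular outgroups (chosen so that homology
#: search and distance trees are informative but far from saturated).
DEFAULT_SPECIES_NEWICK = (
    "((((((DD:0.3,DP:0.3):0.3,DL:0.3):0.3,(PP:0.3,DF:0.3):0.3):0.3,"
    "PhyP:0.6):0.3,AC:0.6):0.3,EH:0.6);"
)

DOMAIN_VOCAB = (
    "PA14", "Dicty_CTDC", "EGF", "TIG", "Kinase", "FOLN",
    "Spore_N", "SAPA", "GATA", "CNH", "LRR", "HisK",
)

GO_VOCAB = tuple(f"GO:{7000000 + i:07d}" for i in range(12))

_N_AA = 20


def default_species_tree() -> dendropy.Tree:
    return read_newick(DEFAULT_SPECIES_NEWICK, rooted=True)


def branch_code(snode) -> str:
    """Stable identifier for a species-tree branch: leaves below, joined."""
    return "+".join(sorted(lf.taxon.label for lf in snode.leaf_iter()))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Rates are per unit branch length (branch lengths are in expected
    substitutions/site); probabilities are per family.
    """

    n_families: int = 100
    dup_rate: float = 0.1
    loss_rate: float = 0.05
    lgt_prob: float = 0.05
    seq_length: int = 200
    sub_rate: float = 1.0
    expr_divergence_prob: float = 0.3
    seed: int = 0
    # expression noise model
    peak_amplitude: float = 500.0
    peak_sigma: float = 1.0
    nb_dispersion: float = 0.1
    library_sigma: float = 0.3
    total_reads_base: int = 1_000_000
    avg_read_length: float = 100.0
    # domain architecture gain/loss, per history branch
    arch_gain_prob: float = 0.03
    arch_loss_prob: float = 0.03
    species_newick: str = DEFAULT_SPECIES_NEWICK

    def __post_init__(self):
        if min(self.dup_rate, self.loss_rate, self.sub_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.seq_length < 10:
            raise ValueError("seq_length must be >= 10")
        for p in (self.lgt_prob, self.expr_divergence_prob,
                  self.arch_gain_prob, self.arch_loss_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def species_tree(self) -> dendropy.Tree:
        return read_newick(self.species_newick, rooted=True)


class HNode:
    """Node of a gene-history tree (the true evolutionary record)."""

    __slots__ = ("kind", "edge_len", "species", "gene_id", "children")

    def __init__(self, kind, edge_len=0.0, species=None, gene_id=None):
        self.kind = kind  # root | speciation | duplication | loss | leaf | transfer
        self.edge_len = edge_len
        self.species = species
        self.gene_id = gene_id
        self.children: list[HNode] = []

    def leaves(self):
        if self.kind == "leaf":
            yield self
            return
        for c in self.children:
            yield from c.leaves()


@dataclass
class FamilyTruth:
    """Simulator event log and derived true relations for one family."""

    family_id: str
    events: list = field(default_factory=list)  # (kind, branch_code, time)
    ortholog_pairs: set = field(default_factory=set)  # frozensets of 2 gene ids
    lgt_genes: set = field(default_factory=set)
    expression_pattern: str = "conserved"
    divergent_species: tuple = ()
    arch_root: tuple = ()
    arch_conserved: dict = field(default_factory=dict)  # gene id -> bool
    resamples: int = 0
    history: HNode | None = None


@dataclass
class Family:
    """One simulated gene family: amoebozoan genes plus outgroup homologs."""

    family_id: str
    records: list = field(default_factory=list)
    outgroup: list = field(default_factory=list)
    truth: FamilyTruth = None
    expression_rows: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# birth-death gene history along the species tree


def _along_branch(parent, snode, t_left, cfg, rng, events):
    """Advance one gene copy along a species-tree branch."""
    t_dup = rng.exponential(1.0 / cfg.dup_rate) if cfg.dup_rate > 0 else math.inf
    t_loss = rng.exponential(1.0 / cfg.loss_rate) if cfg.loss_rate > 0 else math.inf
    t_event = min(t_dup, t_loss)
    if t_event < t_left:
        if t_loss <= t_dup:
            child = HNode("loss", edge_len=t_event)
            parent.children.append(child)
            events.append(("loss", branch_code(snode), round(t_event, 6)))
        else:
            child = HNode("duplication", edge_len=t_event)
            parent.children.append(child)
            events.append(("duplication", branch_code(snode), round(t_event, 6)))
            _along_branch(child, snode, t_left - t_event, cfg, rng, events)
            _along_branch(child, snode, t_left - t_event, cfg, rng, events)
    elif snode.is_leaf():
        parent.children.append(
            HNode("leaf", edge_len=t_left, species=snode.taxon.label)
        )
    else:
        spn = HNode("speciation", edge_len=t_left)
        parent.children.append(spn)
        for child_snode in snode.child_nodes():
            _along_branch(spn, child_snode, child_snode.edge.length, cfg, rng, events)


def _prune(node):
    """Drop lineages without extant descendants; collapse unary nodes."""
    if node.kind == "leaf":
        return node
    if node.kind == "loss":
        return None
    kept = []
    for c in node.children:
        p = _prune(c)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.edge_len += node.edge_len
        return child
    node.children = kept
    return node


def _assign_gene_ids(root, family_id, flag_lgt=False):
    counters: dict[str, int] = {}
    ids = []
    for leaf in root.leaves():
        counters[leaf.species] = counters.get(leaf.species, 0) + 1
        suffix = "L" if flag_lgt else ""
        leaf.gene_id = f"{family_id}_{leaf.species}_{suffix}{counters[leaf.species]}"
        ids.append(leaf.gene_id)
    return ids


def true_ortholog_pairs(root) -> set[frozenset]:
    """Pairs of extant genes whose last common ancestor is a speciation."""
    pairs: set[frozenset] = set()

    def recurse(node):
        if node.kind == "leaf":
            return [node.gene_id]
        child_sets = [recurse(c) for c in node.children]
        if node.kind in ("speciation", "root"):
            for i in range(len(child_sets)):
                for j in range(i + 1, len(child_sets)):
                    for a in child_sets[i]:
                        for b in child_sets[j]:
                            pairs.add(frozenset((a, b)))
        return [g for s in child_sets for g in s]

    recurse(root)
    return pairs


# ---------------------------------------------------------------------------
# sequences


def _random_seq_codes(length, rng):
    return rng.integers(0, _N_AA, size=length)


def _evolve_codes(codes, t, sub_rate, rng):
    p = 1.0 - math.exp(-sub_rate * t)
    mask = rng.random(codes.shape[0]) < p
    out = codes.copy()
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, _N_AA, size=k)) % _N_AA
    return out


def _codes_to_seq(codes) -> str:
    return "".join(AMINO_ACIDS[c] for c in codes)


def _evolve_history(root, root_codes, sub_rate, rng):
    """Assign sequences to extant leaves by descent along the history."""
    def recurse(node, codes):
        if node.kind == "leaf":
            node_seq[node.gene_id] = codes
            return
        for c in node.children:
            recurse(c, _evolve_codes(codes, c.edge_len, sub_rate, rng))

    node_seq: dict[str, np.ndarray] = {}
    recurse(root, root_codes)
    return node_seq


def simulate_family(cfg: SimulationConfig, rng, family_id="F0000") -> Family:
    """Simulate one family: birth–death history, sequences, ground truth.

    The lineage starts as a single copy at the species-tree root; on
    each branch every extant copy duplicates/dies with the configured
    rates (exponential waiting times).  An extinct family is resampled
    (logged in the truth record) so the dataset size is exact.
    """
    stree = cfg.species_tree()
    resamples = 0
    while True:
        events: list = []
        root = HNode("root")
        for child in stree.seed_node.child_nodes():
            _along_branch(root, child, child.edge.length, cfg, rng, events)
        pruned = _prune(root)
        if pruned is not None:
            break
        resamples += 1
        log.info("family %s went extinct; resampling (%d)", family_id, resamples)
    _assign_gene_ids(pruned, family_id)
    root_codes = _random_seq_codes(cfg.seq_length, rng)
    seqs = _evolve_history(pruned, root_codes, cfg.sub_rate, rng)
    records = []
    for leaf in pruned.leaves():
        records.append(
            ProteinRecord(
                id=leaf.gene_id,
                species=leaf.species,
                sequence=_codes_to_seq(seqs[leaf.gene_id]),
                kingdom="amoebozoa",
            )
        )
    truth = FamilyTruth(
        family_id=family_id,
        events=events,
        ortholog_pairs=true_ortholog_pairs(pruned),
        resamples=resamples,
        history=pruned,
    )
    fam = Family(family_id=family_id, records=records, truth=truth)
    fam._root_codes = root_codes
    return fam


# ---------------------------------------------------------------------------
# lateral gene transfer


@dataclass
class DonorPool:
    """Prokaryote donor family (plus distant eukaryote members) with tree."""

    prokaryotes: list
    eukaryotes: list
    tree: dendropy.Tree
    root_codes: np.ndarray = None
    donor_codes: np.ndarray = None


def make_donor_pool(
    cfg: SimulationConfig,
    rng,
    family_id="F0000",
    n_prok: int = 4,
    n_euk: int = 2,
    prok_divergence: float = 0.15,
    euk_stem: float = 1.3,
    euk_radiation: float = 0.3,
) -> DonorPool:
    """Generate a prokaryote gene family with distant eukaryote homologs.

    The eukaryote members form their own clade whose ancestor sits
    ``euk_stem`` substitutions/site from the donor, so a gene
    transferred from the donor is markedly closer to prokaryote
    sequences than to any eukaryote one.
    """
    root_codes = _random_seq_codes(cfg.seq_length, rng)
    proks, euks = [], []
    for k in range(n_prok):
        codes = _evolve_codes(root_codes, prok_divergence, cfg.sub_rate, rng)
        proks.append(ProteinRecord(
            id=f"{family_id}_PK{k + 1}", species=f"PK{k + 1}",
            sequence=_codes_to_seq(codes), kingdom="prokaryote"))
    euk_anc = _evolve_codes(root_codes, euk_stem, cfg.sub_rate, rng)
    for k in range(n_euk):
        codes = _evolve_codes(euk_anc, euk_radiation, cfg.sub_rate, rng)
        euks.append(ProteinRecord(
            id=f"{family_id}_EU{k + 1}", species=f"EU{k + 1}",
            sequence=_codes_to_seq(codes), kingdom="other_eukaryote"))
    newick = "(({}),({}):{});".format(
        ",".join(f"{r.id}:{prok_divergence}" for r in proks),
        ",".join(f"{r.id}:{euk_radiation}" for r in euks),
        euk_stem,
    )
    tree = read_newick(newick, rooted=True)
    donor_codes = _evolve_codes(root_codes, prok_divergence, cfg.sub_rate, rng)
    return DonorPool(proks, euks, tree, root_codes, donor_codes)


def _find_branch(stree, code: str):
    for node in stree.preorder_node_iter():
        if node.parent_node is not None and branch_code(node) == code:
            return node
    raise ValueError(f"no species-tree branch with code '{code}'")


DICTYOSTELIA_STEM = "+".join(sorted(DICTYOSTELIDS))


def inject_lgt(
    family: Family,
    donor_pool: DonorPool,
    cfg: SimulationConfig,
    rng,
    target_branch: str = DICTYOSTELIA_STEM,
) -> Family:
    """Copy a donor sequence onto a species-tree branch.

    The transferred copy lands at the top of ``target_branch`` and
    thereafter duplicates, dies and mutates like a native gene; all
    surviving descendants are flagged as true LGT genes in the family's
    ground truth.
    """
    if not donor_pool.prokaryotes:
        raise ValueError("empty donor pool")
    stree = cfg.species_tree()
    target = _find_branch(stree, target_branch)
    resamples = 0
    while True:
        events: list = []
        tnode = HNode("transfer")
        _along_branch(tnode, target, target.edge.length, cfg, rng, events)
        pruned = _prune(tnode)
        if pruned is not None:
            break
        resamples += 1
    _assign_gene_ids(pruned, family.family_id, flag_lgt=True)
    seqs = _evolve_history(pruned, donor_pool.donor_codes, cfg.sub_rate, rng)
    lgt_records = []
    for leaf in pruned.leaves():
        lgt_records.append(ProteinRecord(
            id=leaf.gene_id, species=leaf.species,
            sequence=_codes_to_seq(seqs[leaf.gene_id]), kingdom="amoebozoa"))
    family.records.extend(lgt_records)
    family.outgroup.extend(donor_pool.prokaryotes)
    family.outgroup.extend(donor_pool.eukaryotes)
    truth = family.truth
    truth.events.append(("transfer", target_branch, 0.0))
    truth.events.extend(events)
    truth.lgt_genes.update(r.id for r in lgt_records)
    truth.ortholog_pairs.update(true_ortholog_pairs(pruned))
    truth.resamples += resamples
    if truth.history is None:
        truth.history = pruned
    return family


def simulate_lgt_family(cfg: SimulationConfig, rng, family_id="F0000") -> Family:
    """A family that exists in Dictyostelia only through a transfer.

    Models the Table-1 scenario: closest homologs are prokaryote, none
    in the unicellular amoebozoa.
    """
    donors = make_donor_pool(cfg, rng, family_id=family_id)
    fam = Family(
        family_id=family_id,
        truth=FamilyTruth(family_id=family_id),
    )
    fam._root_codes = donors.root_codes
    return inject_lgt(fam, donors, cfg, rng)


# ---------------------------------------------------------------------------
# expression


#: Clades eligible for a divergence event: each single dictyostelid, the
#: group-4 clade, and branch I (whose shift realizes the I-vs-II pattern).
DIVERGENCE_CLADES = (
    ("one_species", ("DD",)),
    ("one_species", ("DP",)),
    ("one_species", ("DL",)),
    ("one_species", ("PP",)),
    ("one_species", ("DF",)),
    ("group4_vs_123", ("DD", "DP")),
    ("branchI_vs_II", ("PP", "DF")),
)


def _shifted_peak(peak: int, rng) -> int:
    mag = int(rng.integers(2, 4))  # 2 or 3 stages
    candidates = [p for p in (peak + mag, peak - mag) if 0 <= p <= len(STAGES) - 1]
    if not candidates:
        candidates = [peak + mag if peak + mag <= len(STAGES) - 1 else peak - mag]
    if len(candidates) == 2:
        return candidates[int(rng.integers(0, 2))]
    return candidates[0]


def simulate_expression(
    family: Family,
    cfg: SimulationConfig,
    rng,
    lib_factors=None,
    forced_clade=None,
):
    """Seven-stage read counts for every dictyostelid gene of the family.

    The base profile is a unimodal (Gaussian-shaped) curve peaking at a
    family-specific stage; counts are negative-binomial draws around
    the curve, scaled by a per-sample library size.  With probability
    ``expr_divergence_prob`` one clade's peak is shifted by >= 2 stages
    and the ground truth stores the divergent clade.  ``forced_clade``
    (pattern, species tuple) plants a divergence deterministically.
    """
    peak = int(rng.integers(1, 6))
    pattern, clade = "conserved", ()
    if forced_clade is not None:
        pattern, clade = forced_clade
    elif rng.random() < cfg.expr_divergence_prob:
        pattern, clade = DIVERGENCE_CLADES[int(rng.integers(0, len(DIVERGENCE_CLADES)))]
    shifted = _shifted_peak(peak, rng) if clade else peak
    if lib_factors is None:
        lib_factors = {
            (sp, s): float(np.exp(rng.normal(0.0, cfg.library_sigma)))
            for sp in DICTYOSTELIDS
            for s in range(len(STAGES))
        }
    n_nb = 1.0 / cfg.nb_dispersion if cfg.nb_dispersion > 0 else None
    rows = []
    for rec in sorted(family.records, key=lambda r: r.id):
        if rec.species not in DICTYOSTELIDS:
            continue
        sp_peak = shifted if rec.species in clade else peak
        for s, stage in enumerate(STAGES):
            lib = lib_factors[(rec.species, s)]
            mu = cfg.peak_amplitude * math.exp(
                -((s - sp_peak) ** 2) / (2 * cfg.peak_sigma ** 2)
            ) * lib
            if mu <= 0:
                raw = 0
            elif n_nb is None:  # noise-free mode
                raw = int(round(mu))
            else:
                raw = int(rng.negative_binomial(n_nb, n_nb / (n_nb + mu)))
            rows.append({
                "gene": rec.id,
                "species": rec.species,
                "stage_index": s,
                "stage": stage,
                "raw": raw,
                "total_reads": int(round(cfg.total_reads_base * lib)),
                "avg_read_length": cfg.avg_read_length,
            })
    family.expression_rows = rows
    family.truth.expression_pattern = pattern
    family.truth.divergent_species = tuple(sorted(clade))
    return rows


# ---------------------------------------------------------------------------
# domain architecture


def simulate_architecture(
    family: Family,
    cfg: SimulationConfig,
    rng,
    root_arch=None,
    forced_loss_branches=frozenset(),
):
    """Evolve a token-list domain architecture along the gene history.

    Per history branch a token is gained (random token, random
    position) with ``arch_gain_prob`` and one is lost with
    ``arch_loss_prob``.  Ground truth records whether each extant
    gene's architecture still equals the root's.
    ``forced_loss_branches`` (leaf species codes) force a loss on the
    pendant branch of those species.
    """
    if root_arch is None:
        k = int(rng.integers(1, 5))
        root_arch = [DOMAIN_VOCAB[int(i)] for i in rng.integers(0, len(DOMAIN_VOCAB), k)]
    root_arch = list(root_arch)

    def mutate(arch, leaf_species=None):
        arch = list(arch)
        if rng.random() < cfg.arch_gain_prob:
            pos = int(rng.integers(0, len(arch) + 1))
            arch.insert(pos, DOMAIN_VOCAB[int(rng.integers(0, len(DOMAIN_VOCAB)))])
        forced = leaf_species in forced_loss_branches
        if arch and (forced or rng.random() < cfg.arch_loss_prob):
            arch.pop(int(rng.integers(0, len(arch))))
        return arch

    by_id = {r.id: r for r in family.records}

    def recurse(node, arch):
        if node.kind == "leaf":
            by_id[node.gene_id].architecture = list(arch)
            family.truth.arch_conserved[node.gene_id] = arch == root_arch
            return
        for c in node.children:
            recurse(c, mutate(arch, c.species if c.kind == "leaf" else None))

    root = family.truth.history
    if root.kind == "leaf":
        by_id[root.gene_id].architecture = list(root_arch)
        family.truth.arch_conserved[root.gene_id] = True
    else:
        recurse(root, root_arch)
    family.truth.arch_root = tuple(root_arch)
    return {r.id: list(r.architecture) for r in family.records}


def _assign_misc_annotations(family: Family, rng):
    """Family-level SigP/TM flags and GO terms (shared by all members)."""
    sigp = bool(rng.random() < 0.3)
    tm = bool(rng.random() < 0.3)
    n_go = int(rng.integers(1, 4))
    gos = {GO_VOCAB[int(i)] for i in rng.integers(0, len(GO_VOCAB), n_go)}
    for rec in family.records:
        rec.sigp, rec.tm = sigp, tm
        rec.go_terms = set(gos)


# ---------------------------------------------------------------------------
# dataset bundle


def simulate_dataset(cfg: SimulationConfig, rng=None) -> list[Family]:
    """Simulate ``cfg.n_families`` families (in memory)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lib_factors = {
        (sp, s): float(np.exp(rng.normal(0.0, cfg.library_sigma)))
        for sp in DICTYOSTELIDS
        for s in range(len(STAGES))
    }
    families = []
    for i in range(cfg.n_families):
        fid = f"F{i:04d}"
        if rng.random() < cfg.lgt_prob:
            fam = simulate_lgt_family(cfg, rng, family_id=fid)
        else:
            fam = simulate_family(cfg, rng, family_id=fid)
            # one distant eukaryote (opisthokont) homolog for outgroup search
            codes = _evolve_codes(fam._root_codes, 1.2, cfg.sub_rate, rng)
            fam.outgroup.append(ProteinRecord(
                id=f"{fid}_OP1", species="OP1",
                sequence=_codes_to_seq(codes), kingdom="opisthokonta"))
        simulate_expression(fam, cfg, rng, lib_factors=lib_factors)
        simulate_architecture(fam, cfg, rng)
        _assign_misc_annotations(fam, rng)
        families.append(fam)
    return families


def generate_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full on-disk bundle; byte-identical for identical seed.

    Emits per-species FASTA, outgroup FASTA, annotation/expression/
    species-map/family TSVs, ground-truth TSVs and a manifest listing
    every file with its row count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = simulate_dataset(cfg)

    all_records = [r for f in families for r in f.records]
    outgroup = [r for f in families for r in f.outgroup]
    by_species: dict[str, list] = {}
    for r in all_records:
        by_species.setdefault(r.species, []).append(r)

    files: dict[str, int] = {}

    def _write(name, lines):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write("".join(lines))
        files[name] = sum(1 for ln in lines if ln.strip())

    for sp in sorted(by_species):
        recs = sorted(by_species[sp], key=lambda r: r.id)
        write_fasta(recs, outdir / f"{sp}.fasta")
        files[f"{sp}.fasta"] = len(recs)
    og = sorted(outgroup, key=lambda r: r.id)
    write_fasta(og, outdir / "outgroup.fasta")
    files["outgroup.fasta"] = len(og)

    ann_lines = []
    for r in sorted(all_records + outgroup, key=lambda r: r.id):
        for dom in r.architecture:
            ann_lines.append(f"{r.id}\tdomain\t{dom}\n")
        ann_lines.append(f"{r.id}\tsigp\t{'true' if r.sigp else 'false'}\n")
        ann_lines.append(f"{r.id}\ttm\t{'true' if r.tm else 'false'}\n")
        for go in sorted(r.go_terms):
            ann_lines.append(f"{r.id}\tgo\t{go}\n")
        ann_lines.append(f"{r.id}\tkingdom\t{r.kingdom}\n")
    _write("annotations.tsv", ann_lines)

    expr_lines = ["gene\tspecies\tstage_index\tstage\traw\ttotal_reads\tavg_read_length\n"]
    for fam in families:
        for row in fam.expression_rows:
            expr_lines.append(
                "{gene}\t{species}\t{stage_index}\t{stage}\t{raw}\t"
                "{total_reads}\t{avg_read_length:g}\n".format(**row))
    _write("expression.tsv", expr_lines)

    sm_lines = [f"{r.id}\t{r.species}\n"
                for r in sorted(all_records + outgroup, key=lambda r: r.id)]
    _write("species_map.tsv", sm_lines)

    fam_lines = []
    for fam in families:
        for r in sorted(fam.records + fam.outgroup, key=lambda r: r.id):
            fam_lines.append(f"{r.id}\t{fam.family_id}\n")
    _write("families.tsv", fam_lines)

    truth_orth = ["family\tgene_a\tgene_b\n"]
    truth_lgt = ["family\tgene\n"]
    truth_expr = ["family\tpattern\tdivergent_species\n"]
    truth_arch = ["family\tgene\tconserved\n"]
    truth_events = ["family\tkind\tbranch\ttime\n"]
    for fam in families:
        t = fam.truth
        for pair in sorted(tuple(sorted(p)) for p in t.ortholog_pairs):
            truth_orth.append(f"{fam.family_id}\t{pair[0]}\t{pair[1]}\n")
        for g in sorted(t.lgt_genes):
            truth_lgt.append(f"{fam.family_id}\t{g}\n")
        truth_expr.append(
            f"{fam.family_id}\t{t.expression_pattern}\t{','.join(t.divergent_species)}\n")
        for g in sorted(t.arch_conserved):
            truth_arch.append(
                f"{fam.family_id}\t{g}\t{'true' if t.arch_conserved[g] else 'false'}\n")
        for kind, br, tm in t.events:
            truth_events.append(f"{fam.family_id}\t{kind}\t{br}\t{tm:g}\n")
    _write("truth_orthologs.tsv", truth_orth)
    _write("truth_lgt.tsv", truth_lgt)
    _write("truth_expression.tsv", truth_expr)
    _write("truth_architecture.tsv", truth_arch)
    _write("truth_events.tsv", truth_events)

    (outdir / "species_tree.nwk").write_text(cfg.species_newick + "\n")
    files["species_tree.nwk"] = 1

    manifest = {
        "config": {k: v for k, v in vars(cfg).items() if not k.startswith("_")},
        "files": {
            name: {"rows": files[name],
                   "sha256": hashlib.sha256((outdir / name).read_bytes()).hexdigest()}
            for name in sorted(files)
        },
        "n_families": cfg.n_families,
        "resamples": sum(f.truth.resamples for f in families),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
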