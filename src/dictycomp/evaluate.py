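"""Score pipeline output against simulator ground truth.

Used to benchmark ortholog calling, LGT validation and
expression-divergence pattern recovery on synthetic datasets where the
true evolutionary history is known.
"""

from __future__ import annotations

from pathlib import Path


def read_truth_orthologs(data_dir) -> set[frozenset]:
    pairs = set()
    with open(Path(data_dir) / "truth_orthologs.tsv") as fh:
        next(fh)
        for line in fh:
            _, a, b = line.split()
            pairs.add(frozenset((a, b)))
    return pairs


def read_truth_lgt_families(data_dir, require_dd: bool = False) -> set[str]:
    """Families with an injected transfer.

    With ``require_dd`` only transfers that left a surviving DD
    descendant count — the screen is DD-centric (candidates are focal
    DD genes), so a transfer lost from DD is undetectable by design.
    """
    fams: dict[str, bool] = {}
    with open(Path(data_dir) / "truth_lgt.tsv") as fh:
        next(fh)
        for line in fh:
            fid, gene = line.split()
            has_dd = gene.split("_")[1] == "DD"
            fams[fid] = fams.get(fid, False) or has_dd
    if require_dd:
        return {f for f, dd in fams.items() if dd}
    return set(fams)


def read_truth_expression(data_dir) -> dict[str, str]:
    out = {}
    with open(Path(data_dir) / "truth_expression.tsv") as fh:
        next(fh)
        for line in fh:
            fid, pattern, _ = line.rstrip("\n").split("\t")
            out[fid] = pattern
    return out


def score_orthology(data_dir, profiles, species_map, families) -> dict:
    """Per-(focal, species) precision and recall of ortholog calls.

    A slot is a (focal gene, other species) combination.  Precision:
    of the slots called ortholog, how often is the called gene a true
    ortholog of the focal.  Recall: of the slots where a true ortholog
    exists, how often is one called.
    """
    truth = read_truth_orthologs(data_dir)
    fam_of = {g: fid for fid, genes in families.items() for g in genes}
    n_called = n_tp = n_slots = n_recalled = 0
    for focal, prof in profiles.items():
        members = families.get(fam_of.get(focal), [])
        for sp, call in prof.calls.items():
            if sp == species_map.get(focal):
                continue
            if call.call == "ortholog" and call.gene:
                n_called += 1
                if frozenset((focal, call.gene)) in truth:
                    n_tp += 1
            has_true = any(species_map.get(g) == sp
                           and frozenset((focal, g)) in truth for g in members)
            if has_true:
                n_slots += 1
                if call.call == "ortholog" and frozenset((focal, call.gene)) in truth:
                    n_recalled += 1
    return {
        "precision": n_tp / n_called if n_called else float("nan"),
        "recall": n_recalled / n_slots if n_slots else float("nan"),
        "n_called": n_called,
        "n_slots": n_slots,
    }


def score_lgt(data_dir, verdicts, families) -> dict:
    """Sensitivity (true transfers recovered as yes) and false yes count."""
    truth = read_truth_lgt_families(data_dir, require_dd=True)
    any_transfer = read_truth_lgt_families(data_dir)
    fam_of_focal = {}
    for fid, genes in families.items():
        for g in genes:
            fam_of_focal[g] = fid
    yes_families = {fam_of_focal[v.gene_id] for v in verdicts if v.verdict == "yes"}
    n_clean = len(families) - len(any_transfer)
    recovered = len(yes_families & truth)
    false_yes = len(yes_families - any_transfer)
    return {
        "sensitivity": recovered / len(truth) if truth else float("nan"),
        "specificity": 1.0 - (false_yes / n_clean) if n_clean else float("nan"),
        "n_true_transfers": len(truth),
        "n_clean": n_clean,
        "false_yes": false_yes,
    }


def score_expression(data_dir, divergence) -> dict:
    """Fraction of families whose divergence pattern matches the truth."""
    truth = read_truth_expression(data_dir)
    n = agree = 0
    for fid, true_pattern in truth.items():
        pred = divergence.get(fid)
        n += 1
        if pred is not None and pred.pattern == true_pattern:
            agree += 1
    return {"accuracy": agree / n if n else float("nan"), "n_families": n}
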