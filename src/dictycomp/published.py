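"""Published summary tables for *D. discoideum* developmental genes.

Two printed tables from the study this pipeline operationalizes, used
as worked examples and regression anchors:

* the LGT-candidate evidence table — the 11 DD genes whose closest
  homologs are prokaryote, with the BBH criterion, the sister-group
  verdicts of two independent tree inferences, and the printed verdict;
* the limited-conservation table — the 37 DD genes confined to DD,
  group 4 (DD+DP) or branch II (DD+DP+DL), with their signal-peptide
  (S) / transmembrane (T) annotations.
"""

from __future__ import annotations

from .io_formats import ProteinRecord
from .lgt import LGTEvidence, lgt_verdict
from .orthology import ConservationCategory, ConservationProfile

#: gene, BBH-with-prokaryote, sister-prokaryote by method 1 (Bayesian)
#: and method 2 (ML), contaminant-suspect flag, printed verdict, note.
#: dgcA is the contaminant-lookalike: BBH fails because the top database
#: hits are bacterial contaminants of eukaryote genomes, yet the gene is
#: present in all dictyostelid genomes and transcribed.
LGT_EVIDENCE_TABLE = (
    ("acgA", False, False, False, False, "no", ""),
    ("cadA", False, False, False, False, "no", "To cadC"),
    ("chlA", True, True, True, False, "yes", ""),
    ("dgcA", False, True, True, True, "yes", ""),
    ("dhkA", False, False, False, False, "no", ""),
    ("dhkB", False, False, False, False, "no", ""),
    ("dhkC", False, True, True, False, "unlikely", ""),
    ("dokA", True, True, True, False, "yes", ""),
    ("iptA", True, True, True, False, "yes", ""),
    ("phyA", False, False, True, False, "unlikely", ""),
    ("ppk1", False, False, True, False, "unlikely", ""),
)


def lgt_decision_table_agreement() -> dict:
    """Apply the verdict logic to the printed evidence columns.

    Returns the number of rows, the number reproduced exactly and the
    number of printed 'yes' verdicts recovered.
    """
    n = agree = yes_total = yes_found = 0
    for gene, bbh, m1, m2, contaminant, printed, note in LGT_EVIDENCE_TABLE:
        ev = LGTEvidence(
            gene_id=gene, bbh_prokaryote=bbh, sister_prok_method1=m1,
            sister_prok_method2=m2, contaminant_suspect=contaminant,
            present_all_dicty=contaminant, transcribed=contaminant, note=note)
        v = lgt_verdict(ev)
        n += 1
        if v.verdict == printed:
            agree += 1
        if printed == "yes":
            yes_total += 1
            if v.verdict == "yes":
                yes_found += 1
    return {"rows": n, "reproduced": agree,
            "yes_printed": yes_total, "yes_reproduced": yes_found}


#: gene, signal-peptide/transmembrane annotation (S, T, S+T or -), and
#: the conservation label: DD only, group 4 ("4") or branch II ("II").
LIMITED_CONSERVATION_TABLE = (
    ("ampA", "S", "4"),
    ("carB", "T", "4"),
    ("carC", "T", "4"),
    ("carD", "T", "4"),
    ("catB", "-", "II"),
    ("chtC", "T", "4"),
    ("comC", "S+T", "4"),
    ("comH", "-", "DD"),
    ("cotA", "S", "II"),
    ("cotB", "S", "4"),
    ("cotC", "S", "4"),
    ("cotE", "S", "II"),
    ("ctnB", "S", "4"),
    ("ctnC", "S", "4"),
    ("DDB_G0268314", "T", "DD"),
    ("DDB_G0279727", "S", "4"),
    ("dtfA", "-", "DD"),
    ("ecmA", "S", "DD"),
    ("iptA", "-", "4"),
    ("manH", "-", "DD"),
    ("pde4", "T", "II"),
    ("pdiA", "S", "DD"),
    ("ponA", "-", "DD"),
    ("psiA", "S", "II"),
    ("psiF", "S", "4"),
    ("psiN", "S", "4"),
    ("pslA", "-", "DD"),
    ("rtoA", "S", "4"),
    ("smlA", "-", "4"),
    ("srsA", "T", "II"),
    ("sslA1", "-", "DD"),
    ("tagB", "T", "DD"),
    ("tgrB1", "S+T", "4"),
    ("tgrC1", "S+T", "DD"),
    ("tgrD1", "S+T", "DD"),
    ("zak1", "-", "DD"),
    ("zak2", "-", "DD"),
)

_ONLY_TO_CALLS = {
    "DD": ("DD",),
    "4": ("DD", "DP"),
    "II": ("DD", "DP", "DL"),
}


def limited_conservation_inputs():
    """Build profiles and records for the limited-conservation summary."""
    profiles, records = [], []
    for gene, st, only in LIMITED_CONSERVATION_TABLE:
        present = _ONLY_TO_CALLS[only]
        calls = {sp: ("ortholog" if sp in present else "absent")
                 for sp in ("DD", "DP", "DL", "PP", "DF", "PhyP", "AC", "EH")}
        prof = ConservationProfile(focal=gene, calls=calls)
        prof.category = ConservationCategory(
            category="DD_only" if only == "DD" else only, only=only,
            all5_ortholog=False, multi_only=True, uni_plus_multi=False,
            n_dicty_ortholog=len(present), n_dicty_present=len(present))
        profiles.append(prof)
        records.append(ProteinRecord(
            id=gene, species="DD", sequence="M",
            sigp="S" in st, tm="T" in st))
    return profiles, records
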