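"""Rule-based functional mining: transcription factors, detoxification
families, and sex-determination candidates.

TF calling is GO-gated: a transcript is a transcription factor only if it
carries at least one qualifying GO term (sequence-specific DNA-binding TF
activity, regulation of DNA-templated transcription, or RNA-Pol-II distal
enhancer binding); its Pfam domains then assign one of eleven named domain
classes by a fixed priority order (shipped as an editable table), defaulting
to "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import load_data_table, normalize_cyp_family

DEFAULT_TF_GO = frozenset({"GO:0003700", "GO:0006355", "GO:0003705"})

TF_CLASS_ORDER = ["Zinc finger", "Homeobox", "Helix-loop-helix", "BTB/POZ",
                  "Bzip", "Myb", "WD40", "Basal TFs", "Fork-head",
                  "Bromodomain", "Helicase", "other"]

GST_N_DOMAINS = ("GST_N",)
GST_C_DOMAINS = ("GST_C",)
UGT_DOMAINS = ("UDPGT", "UDP-glucuronosyl")
P450_DOMAINS = ("p450",)


def _split(field) -> list[str]:
    if isinstance(field, (list, tuple, set)):
        return [str(v) for v in field]
    if pd.isna(field) or not str(field):
        return []
    return [v.strip() for v in str(field).split(",") if v.strip()]


def load_tf_class_map() -> list[tuple[str, str]]:
    """(pattern, class) pairs in priority order."""
    table = load_data_table("tf_class_map.tsv")
    return list(table.itertuples(index=False, name=None))


def _match_class(domains: list[str], class_map: list[tuple[str, str]]) -> str:
    for pattern, tf_class in class_map:
        for domain in domains:
            if pattern.lower() in domain.lower():
                return tf_class
    return "other"


def classify_tf(annotations: pd.DataFrame, go_set=DEFAULT_TF_GO,
                class_map: list[tuple[str, str]] | None = None):
    """TF calls and the per-class count table.

    Returns (calls, table): ``calls`` has one row per TF transcript with its
    domain class; ``table`` reports count and relative percentage (one
    decimal, rounded) per class, all classes present, percentages over the
    classified-transcript total.
    """
    if class_map is None:
        class_map = load_tf_class_map()
    go_set = set(go_set)
    rows = []
    for _, rec in annotations.iterrows():
        if go_set & set(_split(rec["go_terms"])):
            rows.append({
                "transcript_id": rec["transcript_id"],
                "gene_id": rec.get("gene_id", ""),
                "tf_class": _match_class(_split(rec["pfam_domains"]), class_map),
            })
    calls = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "tf_class"])
    counts = calls["tf_class"].value_counts()
    total = int(counts.sum())
    table = pd.DataFrame({
        "count": [int(counts.get(c, 0)) for c in TF_CLASS_ORDER],
    }, index=pd.Index(TF_CLASS_ORDER, name="tf_class"))
    table["percent"] = (100.0 * table["count"] / total).round(1) if total else 0.0
    return calls, table


@dataclass
class DetoxTables:
    p450: pd.DataFrame   # unigene-level CYP family assignments
    gst: pd.DataFrame    # unigene-level {both_domains, N_only, C_only}
    ugt: pd.DataFrame    # unigene-level UGT calls


def _has_domain(domains, patterns) -> bool:
    return any(p.lower() in d.lower() for d in domains for p in patterns)


def classify_detox(annotations: pd.DataFrame) -> DetoxTables:
    """Detoxification-family tables at unigene level.

    P450 unigenes are assigned CYP families from the annotated gene name
    (Roman-numeral family labels are normalized to Arabic); GST unigenes are
    split by presence of N-/C-terminal GST domains across their isoforms;
    UGT unigenes are counted by domain presence.
    """
    per_gene: dict[str, dict] = {}
    for _, rec in annotations.iterrows():
        gene = rec["gene_id"]
        info = per_gene.setdefault(gene, {"domains": set(), "names": set(),
                                          "transcripts": 0})
        info["domains"].update(_split(rec["pfam_domains"]))
        name = rec.get("blast_gene_name")
        if isinstance(name, str) and name:
            info["names"].add(name)
        info["transcripts"] += 1

    p450_rows, gst_rows, ugt_rows = [], [], []
    for gene, info in per_gene.items():
        domains = info["domains"]
        families = {f for f in (normalize_cyp_family(n) for n in info["names"]) if f}
        if families or _has_domain(domains, P450_DOMAINS):
            family = sorted(families)[0] if families else "unassigned"
            p450_rows.append({"gene_id": gene, "family": family,
                              "n_transcripts": info["transcripts"]})
        has_n = _has_domain(domains, GST_N_DOMAINS)
        has_c = _has_domain(domains, GST_C_DOMAINS)
        if has_n or has_c:
            cls = "both_domains" if (has_n and has_c) else ("N_only" if has_n else "C_only")
            gst_rows.append({"gene_id": gene, "gst_class": cls})
        if _has_domain(domains, UGT_DOMAINS):
            ugt_rows.append({"gene_id": gene})
    return DetoxTables(
        p450=pd.DataFrame(p450_rows, columns=["gene_id", "family", "n_transcripts"]),
        gst=pd.DataFrame(gst_rows, columns=["gene_id", "gst_class"]),
        ugt=pd.DataFrame(ugt_rows, columns=["gene_id"]),
    )


def detox_summary(tables: DetoxTables) -> pd.DataFrame:
    """Family-level counts in the layout of the detoxification table."""
    rows = [{"gene_class": "P450", "family": fam, "n": int(n)}
            for fam, n in tables.p450["family"].value_counts().sort_index().items()]
    rows.append({"gene_class": "GST", "family": "glutathione S-transferases",
                 "n": int(len(tables.gst))})
    rows.append({"gene_class": "UGT", "family": "UDP-glucuronosyltransferases",
                 "n": int(len(tables.ugt))})
    return pd.DataFrame(rows)


def match_sex_determination(hits: pd.DataFrame, peptide_map: pd.DataFrame,
                            evalue_max: float = 1e-10) -> pd.DataFrame:
    """Transcripts matching a sex-determination gene panel.

    A transcript matches a panel gene iff any hit to any of that gene's
    peptides has e-value <= ``evalue_max``. Every panel gene is reported,
    including those with zero matching transcripts.
    """
    pep_gene = peptide_map.set_index("peptide_id")["gene"]
    df = hits.copy()
    df["panel_gene"] = df["sseqid"].map(pep_gene)
    df = df[df["panel_gene"].notna() & (df["evalue"] <= evalue_max)]
    matched = df.groupby("panel_gene")["qseqid"].agg(lambda s: sorted(set(s)))
    genes = list(dict.fromkeys(peptide_map["gene"]))
    rows = []
    for gene in genes:
        tx = matched.get(gene, [])
        rows.append({"gene": gene, "n_transcripts": len(tx),
                     "transcripts": ",".join(tx)})
    return pd.DataFrame(rows)
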