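"""Census aggregation, membrane and sensor statistics, gene neighborhoods.

Per-taxon census rows mirror the layout of a published two-component-system
survey table: genome and protein totals, histidine-kinase counts (hybrids
included), response-regulator counts, stand-alone-REC counts with their
percentage of all regulators, and DNA-binding (HTH-subclass) counts.
Percentages are rounded to the nearest integer, half away from zero; zero
counts render as an em dash in the formatted table.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Architecture, GeneFeature, NeighborhoodCall, ProteinRecord, TCSCall

log = logging.getLogger(__name__)

CENSUS_COLUMNS = (
    "taxon",
    "n_genomes",
    "n_proteins",
    "n_HK",
    "n_RR",
    "n_REC_only",
    "pct_REC_only",
    "n_HTH",
)

DEFAULT_OPERON_MAX_GAP = 200
DEFAULT_NEIGHBOR_WINDOW = 5

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
DEFAULT_TM_WINDOW = 19
DEFAULT_TM_CUTOFF = 1.6


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (printed-table convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# -- census ----------------------------------------------------------------


def build_census(
    calls: Iterable[TCSCall],
    proteins: Iterable[ProteinRecord],
    taxonomy: Mapping[str, str],
    genome_counts: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Aggregate classification calls into per-taxon census rows + totals.

    ``taxonomy`` maps genome id -> taxon; unmapped genomes land in an
    "unclassified" row with a warning.  Proteins flagged
    ``excluded_divergent`` are omitted from every count.  ``genome_counts``
    can supply the number of genomes per taxon when the protein set does
    not cover every genome.
    """
    proteins = list(proteins)
    genome_of = {p.protein_id: p.genome_id for p in proteins}

    def taxon_of(genome: str) -> str:
        if genome not in taxonomy:
            log.warning("genome %r missing from taxonomy; counted as unclassified", genome)
            return "unclassified"
        return taxonomy[genome]

    per_taxon: dict[str, dict[str, float]] = {}

    def row(taxon: str) -> dict[str, float]:
        return per_taxon.setdefault(
            taxon,
            {"n_genomes": 0, "n_proteins": 0, "n_HK": 0, "n_RR": 0,
             "n_REC_only": 0, "n_HTH": 0},
        )

    genomes_by_taxon: dict[str, set[str]] = {}
    for p in proteins:
        taxon = taxon_of(p.genome_id)
        row(taxon)["n_proteins"] += 1
        genomes_by_taxon.setdefault(taxon, set()).add(p.genome_id)
    for taxon, genomes in genomes_by_taxon.items():
        row(taxon)["n_genomes"] = (
            genome_counts.get(taxon, len(genomes)) if genome_counts else len(genomes)
        )

    for call in calls:
        if call.excluded:
            continue
        genome = genome_of.get(call.protein_id)
        if genome is None:
            continue
        r = row(taxon_of(genome))
        if call.is_hk:
            r["n_HK"] += 1
        elif call.is_rr:
            r["n_RR"] += 1
            if call.rr_subclass == "REC_only":
                r["n_REC_only"] += 1
            elif call.rr_subclass == "transcriptional_HTH":
                r["n_HTH"] += 1

    rows = [
        {"taxon": taxon, **counts} for taxon, counts in sorted(per_taxon.items())
    ]
    return build_census_from_rows(pd.DataFrame(rows))


def build_census_from_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Finish a census from pre-counted per-taxon rows.

    Adds the REC-only percentage column (NaN where a taxon has no
    regulators) and the column-wise totals row.  This is also the path a
    printed census table takes when re-aggregated from its own rows.
    """
    df = rows.copy()
    for col in ("n_genomes", "n_proteins", "n_HK", "n_RR", "n_REC_only", "n_HTH"):
        if col not in df.columns:
            df[col] = 0
        df[col] = df[col].astype(int)
    df["pct_REC_only"] = [
        float(round_half_away(100.0 * ro / rr)) if rr > 0 else np.nan
        for ro, rr in zip(df["n_REC_only"], df["n_RR"])
    ]
    totals = {
        "taxon": "Total",
        **{c: int(df[c].sum()) for c in
           ("n_genomes", "n_proteins", "n_HK", "n_RR", "n_REC_only", "n_HTH")},
    }
    tot_rr = totals["n_RR"]
    totals["pct_REC_only"] = (
        float(round_half_away(100.0 * totals["n_REC_only"] / tot_rr)) if tot_rr else np.nan
    )
    df = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    return df[list(CENSUS_COLUMNS)]


def format_census(census: pd.DataFrame, dash: str = "—") -> pd.DataFrame:
    """Render a census for printing: zeros and undefined percentages as a dash."""
    out = census.copy()
    for col in ("n_HK", "n_RR", "n_REC_only", "n_HTH"):
        out[col] = [dash if v == 0 else str(int(v)) for v in out[col]]
    out["pct_REC_only"] = [
        dash if (isinstance(v, float) and math.isnan(v)) else str(int(v))
        for v in out["pct_REC_only"]
    ]
    return out


# -- per-genome statistics -------------------------------------------------


def genome_stats(
    calls: Iterable[TCSCall],
    proteins: Iterable[ProteinRecord],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-genome kinase/regulator counts plus size-scaling correlations.

    Returns the per-genome table (counts, RR/HK ratio, TCS percentage of
    ORFs) and a summary dict with Pearson and Spearman correlations of the
    total TCS count against genome protein count across genomes.
    """
    proteins = list(proteins)
    genome_of = {p.protein_id: p.genome_id for p in proteins}
    orfs: dict[str, int] = {}
    for p in proteins:
        orfs[p.genome_id] = orfs.get(p.genome_id, 0) + 1

    counts: dict[str, dict[str, int]] = {
        g: {"n_HK": 0, "n_RR": 0, "n_HisKA_no_HATPase": 0} for g in orfs
    }
    for call in calls:
        if call.excluded:
            continue
        g = genome_of.get(call.protein_id)
        if g is None:
            continue
        if call.is_hk:
            counts[g]["n_HK"] += 1
        elif call.is_rr:
            counts[g]["n_RR"] += 1
        elif call.category == "HisKA_no_HATPase":
            counts[g]["n_HisKA_no_HATPase"] += 1

    rows = []
    for g in sorted(orfs):
        c = counts[g]
        n_tcs = c["n_HK"] + c["n_RR"]
        rows.append(
            {
                "genome_id": g,
                "n_proteins": orfs[g],
                "n_HK": c["n_HK"],
                "n_RR": c["n_RR"],
                "n_HisKA_no_HATPase": c["n_HisKA_no_HATPase"],
                "rr_hk_ratio": c["n_RR"] / c["n_HK"] if c["n_HK"] else np.nan,
                "tcs_pct_of_orfs": 100.0 * n_tcs / orfs[g] if orfs[g] else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    summary: dict[str, float] = {"pearson_r": np.nan, "spearman_rho": np.nan}
    if len(table) >= 3:
        tcs = table["n_HK"] + table["n_RR"]
        size = table["n_proteins"]
        if tcs.nunique() > 1 and size.nunique() > 1:
            summary["pearson_r"] = float(stats.pearsonr(size, tcs).statistic)
            summary["spearman_rho"] = float(stats.spearmanr(size, tcs).statistic)
    return table, summary


# -- membrane localisation -------------------------------------------------


def predict_tm(
    sequence: str,
    window: int = DEFAULT_TM_WINDOW,
    cutoff: float = DEFAULT_TM_CUTOFF,
) -> list[tuple[int, int]]:
    """Kyte-Doolittle sliding-window transmembrane-segment prediction.

    A window of ``window`` residues whose mean hydropathy exceeds
    ``cutoff`` calls a membrane-spanning stretch; overlapping windows are
    merged into maximal segments (1-based inclusive coordinates).
    """
    n = len(sequence)
    if n < window:
        return []
    values = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in sequence.upper()])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    hits = np.flatnonzero(means > cutoff)
    segments: list[tuple[int, int]] = []
    for idx in hits:
        start, end = idx + 1, idx + window  # 1-based inclusive
        if segments and start <= segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], end)
        else:
            segments.append((start, end))
    return segments


def membrane_fraction(
    calls: Iterable[TCSCall],
    proteins: Mapping[str, ProteinRecord],
    use_prediction_fallback: bool = True,
    hk_only: bool = True,
    strict: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Fraction of histidine kinases with no transmembrane segments.

    TM segments are taken from the protein record when present; otherwise
    they are predicted from the sequence.  A protein with neither is
    counted as cytoplasmic by default (TMHMM-style tables list only
    proteins with helices); with ``strict`` it is excluded from the
    denominator with a warning.  Kinase-dead (HisKA-without-HATPase)
    proteins never enter the denominator.
    """
    rows = []
    for call in calls:
        if hk_only and not call.is_hk:
            continue
        prot = proteins.get(call.protein_id)
        if prot is None:
            continue
        if prot.tm_segments:
            n_tm = len(prot.tm_segments)
        elif prot.sequence is not None and use_prediction_fallback:
            n_tm = len(predict_tm(prot.sequence))
        elif strict:
            log.warning(
                "protein %r has neither TM data nor sequence; excluded", call.protein_id
            )
            continue
        else:
            n_tm = 0
        rows.append({"protein_id": call.protein_id, "n_tm_segments": n_tm})
    table = pd.DataFrame(rows, columns=["protein_id", "n_tm_segments"])
    if len(table) == 0:
        return float("nan"), table
    fraction = float((table["n_tm_segments"] == 0).mean())
    return fraction, table


# -- sensor tallies --------------------------------------------------------

NAMED_SENSORS = ("MEDS", "PocR", "Cache", "HisKA_7TM", "HisKA_4TM")


def sensor_tally(
    calls: Iterable[TCSCall],
    architectures: Mapping[str, Architecture],
) -> pd.DataFrame:
    """Per-kinase sensor-domain booleans (PAS, GAF, both, named sensors)."""
    rows = []
    for call in calls:
        if not call.is_hk:
            continue
        arch = architectures.get(call.protein_id)
        if arch is None:
            continue
        names = [s.domain_name for s in arch.segments]
        has_pas = any(n.upper().startswith("PAS") for n in names)
        has_gaf = any(n.upper().startswith("GAF") for n in names)
        row = {
            "protein_id": call.protein_id,
            "has_PAS": has_pas,
            "has_GAF": has_gaf,
            "has_both": has_pas and has_gaf,
        }
        for sensor in NAMED_SENSORS:
            row[f"has_{sensor}"] = any(
                n.lower().startswith(sensor.lower()) if sensor == "Cache"
                else n.lower() == sensor.lower()
                for n in names
            )
        rows.append(row)
    cols = ["protein_id", "has_PAS", "has_GAF", "has_both"] + [
        f"has_{s}" for s in NAMED_SENSORS
    ]
    return pd.DataFrame(rows, columns=cols)


# -- gene neighborhoods ----------------------------------------------------


def intergenic_distance(upstream: GeneFeature, downstream: GeneFeature) -> int:
    """Nucleotides strictly between two genes in coordinate order."""
    return max(0, downstream.start - upstream.end - 1)


def find_neighbors(
    features: Sequence[GeneFeature],
    calls: Mapping[str, TCSCall],
    max_gap: int = DEFAULT_OPERON_MAX_GAP,
    window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> tuple[list[NeighborhoodCall], set[str]]:
    """Adjacency relations between genes plus chemotaxis-association flags.

    Adjacent co-oriented genes within ``max_gap`` nucleotides form
    ``same_operon_adjacent`` pairs; adjacent head-to-head genes (strands
    "-" then "+" in coordinate order) are ``divergent``.  A stand-alone-REC
    regulator within ``window`` genes of a CheA-type kinase or a CheB
    regulator inside the same operon run is flagged chemotaxis-associated
    (the returned set holds the flagged protein ids; flags are also set on
    the calls in place).
    """
    by_contig: dict[tuple[str, str], list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault((f.genome_id, f.contig), []).append(f)

    relations: list[NeighborhoodCall] = []
    chemotaxis: set[str] = set()
    for (genome, contig), genes in by_contig.items():
        genes = sorted(genes, key=lambda g: (g.start, g.end))
        runs: list[list[int]] = [[0]] if genes else []
        for i in range(len(genes) - 1):
            a, b = genes[i], genes[i + 1]
            dist = intergenic_distance(a, b)
            relation = None
            if a.strand == b.strand and dist <= max_gap:
                relation = "same_operon_adjacent"
            elif a.strand == "-" and b.strand == "+":
                relation = "divergent"
            if relation:
                relations.append(
                    NeighborhoodCall(
                        genome_id=genome,
                        contig=contig,
                        protein_a=a.protein_id,
                        protein_b=b.protein_id,
                        relation=relation,
                        intergenic_distance=dist,
                    )
                )
            if a.strand == b.strand and dist <= max_gap:
                runs[-1].append(i + 1)
            else:
                runs.append([i + 1])

        for run in runs:
            anchors = []
            rec_only = []
            for pos_in_run, gi in enumerate(run):
                call = calls.get(genes[gi].protein_id)
                if call is None:
                    continue
                if "cheA_like" in call.flags or call.rr_subclass == "CheB":
                    anchors.append(pos_in_run)
                if call.rr_subclass == "REC_only":
                    rec_only.append((pos_in_run, call))
            for pos_in_run, call in rec_only:
                if any(abs(pos_in_run - a) <= window for a in anchors):
                    call.flags.add("chemotaxis_associated")
                    chemotaxis.add(call.protein_id)
    return relations, chemotaxis


def neighbors_table(relations: Sequence[NeighborhoodCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.genome_id, r.contig, r.protein_a, r.protein_b, r.relation,
             r.intergenic_distance)
            for r in relations
        ],
        columns=["genome_id", "contig", "protein_a", "protein_b", "relation",
                 "intergenic_distance"],
    )
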