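"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline is exercised against data produced
here: a three-species two-color microarray time course with planted
conserved / species-specific / divergent fold changes, a 2x2 cycloheximide
(CHX) co-treatment factorial with planted primary and secondary responses,
and promoter sequences with planted dioxin response element (DRE) cores on a
rigorously core-free background.  Each generator is a pure function of its
configuration and seed, and returns a truth table sufficient to score the
corresponding classifier without re-reading intensities or sequences.

The defaults emulate the study design being modelled: seven-point time
courses (1-48 h), three replicates with dye-swap labelings (six arrays per
condition), log2 effects of magnitude 2 against residual noise of SD 0.2,
and an intensity-dependent dye bias that flips sign on dye swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionTable, FormatError, PromoterRecord

DEFAULT_TIMES = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)
DEFAULT_SPECIES = ("human", "mouse", "rat")

CATEGORIES = ("null", "conserved_up", "conserved_down", "specific", "divergent")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def default_dye_bias(a: np.ndarray) -> np.ndarray:
    """Smooth cubic dye bias as a function of mean log2 intensity A.

    Amplitude ~0.4 log2 units across the intensity range, the magnitude of
    curvature two-color arrays typically show before normalization.
    """
    x = (np.asarray(a) - 10.0) / 3.0
    return 0.4 * x - 0.25 * x**3


# ---------------------------------------------------------------------------
# Cross-species expression time course
# ---------------------------------------------------------------------------


@dataclass
class ExperimentTruth:
    """Planted per-(species, gene) effects and ortholog-group categories."""

    genes: pd.DataFrame  # species, gene_id, group_id, category, effect_log2
    times: tuple[float, ...]

    def effects_for(self, species: str) -> pd.Series:
        sub = self.genes[self.genes["species"] == species]
        return sub.set_index("gene_id")["effect_log2"]

    def group_categories(self) -> pd.Series:
        """Category per ortholog group (constant within a group by design)."""
        sub = self.genes[self.genes["group_id"] != ""]
        return sub.groupby("group_id")["category"].first()


def _spread_conditions(
    rng: np.random.Generator,
    species: str,
    genes: pd.DataFrame,
    times: tuple[float, ...],
    n_reps: int,
    noise_sd: float,
    dye_bias,
    treatment: str = "TCDD",
    control: str = "vehicle",
):
    """Simulate two-channel arrays for one species across times x reps x labelings.

    Returns (intensity DataFrame keyed by sample id, sample-sheet rows).
    Labeling 1 puts the treated sample on Cy5; labeling 2 swaps the dyes, so
    the raw log ratio log2(Cy5/Cy3) carries the biological effect with
    opposite sign while the intensity-dependent dye bias keeps its sign.
    """
    n = len(genes)
    base_a = rng.uniform(7.0, 13.0, size=n)  # per-probe mean log2 intensity
    effects = genes["effect_log2"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    sheet_rows: list[dict] = []
    contrast_tag = treatment.replace("+", "")
    for t in times:
        for rep in range(1, n_reps + 1):
            for labeling in (1, 2):
                tag = f"{species}_{contrast_tag}_t{t:g}_r{rep}_l{labeling}"
                array_id = f"arr_{tag}"
                treated_on_cy5 = labeling == 1
                m_true = effects + rng.normal(0.0, noise_sd, size=n)
                a = base_a + rng.normal(0.0, 0.1, size=n)
                sign = 1.0 if treated_on_cy5 else -1.0
                m_dye = sign * m_true + dye_bias(a)
                cy5 = 2.0 ** (a + m_dye / 2.0)
                cy3 = 2.0 ** (a - m_dye / 2.0)
                treated_int, control_int = (
                    (cy5, cy3) if treated_on_cy5 else (cy3, cy5)
                )
                s_treated = f"{tag}_{treatment}"
                s_control = f"{tag}_{control}"
                cols[s_treated] = treated_int
                cols[s_control] = control_int
                sheet_rows.append(
                    dict(
                        sample_id=s_treated,
                        species=species,
                        treatment=treatment,
                        time_hr=t,
                        dye="Cy5" if treated_on_cy5 else "Cy3",
                        replicate=rep,
                        array_id=array_id,
                    )
                )
                sheet_rows.append(
                    dict(
                        sample_id=s_control,
                        species=species,
                        treatment=control,
                        time_hr=t,
                        dye="Cy3" if treated_on_cy5 else "Cy5",
                        replicate=rep,
                        array_id=array_id,
                    )
                )
    values = pd.DataFrame(cols, index=genes["probe_id"].to_numpy())
    return values, sheet_rows


def generate_experiment(
    n_genes: int = 300,
    frac_3way: float = 0.4,
    frac_2way: float = 0.2,
    proportions: dict[str, float] | None = None,
    effect_log2: float = 2.0,
    effect_sigma: float = 0.0,
    noise_sd: float = 0.2,
    dye_bias=default_dye_bias,
    n_reps: int = 3,
    times: tuple[float, ...] = DEFAULT_TIMES,
    species: tuple[str, ...] = DEFAULT_SPECIES,
    seed: int = 0,
):
    """Simulate the three-species TCDD time course with planted categories.

    ``proportions`` assigns categories to the three-way ortholog groups
    (conserved responses same sign in all species; divergent responses have
    one species with opposite sign; specific responses are confined to one
    species).  Genes outside three-way groups are null.  Effect magnitudes
    are ``effect_log2`` (lognormally jittered when ``effect_sigma`` > 0).

    Returns ``(ExpressionTable, sample_sheet, ortholog_table, ExperimentTruth)``.
    """
    if proportions is None:
        proportions = {
            "null": 0.70,
            "conserved_up": 0.10,
            "conserved_down": 0.05,
            "specific": 0.10,
            "divergent": 0.05,
        }
    unknown = set(proportions) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"category proportions must sum to 1, got {total}")
    n3 = int(round(frac_3way * n_genes))
    n2 = int(round(frac_2way * n_genes))
    nonnull = 1.0 - proportions.get("null", 0.0)
    if nonnull > 1e-12 and n3 == 0:
        raise ValueError(
            "non-null category proportions require three-way ortholog groups "
            "(frac_3way > 0)"
        )
    if len(species) < 2:
        if proportions.get("divergent", 0.0) > 0:
            raise ValueError("divergent responses need >= 2 species")
        n2 = 0  # no ortholog pairs exist in a single-species design
    rng = np.random.default_rng(seed)

    # Ortholog structure: first n3 gene slots per species are 3-way groups,
    # the next n2 are 2-way groups cycling over species pairs, the rest
    # are unmatched.
    prefixes = {"human": "hs", "mouse": "mm", "rat": "rn"}
    gene_ids = {
        sp: [f"{prefixes.get(sp, sp[:2])}_g{i:05d}" for i in range(n_genes)]
        for sp in species
    }
    orth_rows: list[dict] = []
    group_of: dict[tuple[str, str], str] = {}
    pairs = [(species[i], species[j]) for i in range(len(species)) for j in range(i + 1, len(species))]
    gid = 0
    for i in range(n3):
        gid += 1
        group = str(1000 + gid)
        if len(species) >= 2:  # a one-species group is not an ortholog group
            for sp in species:
                orth_rows.append(
                    dict(group_id=group, species=sp, gene_id=gene_ids[sp][i])
                )
                group_of[(sp, gene_ids[sp][i])] = group
    for i in range(n2):
        gid += 1
        group = str(1000 + gid)
        pa, pb = pairs[i % len(pairs)]
        for sp in (pa, pb):
            orth_rows.append(
                dict(group_id=group, species=sp, gene_id=gene_ids[sp][n3 + i])
            )
            group_of[(sp, gene_ids[sp][n3 + i])] = group
    ortholog_table = pd.DataFrame(orth_rows, columns=["group_id", "species", "gene_id"])

    # Category per 3-way group, sampled at the stated proportions.
    cats = list(proportions)
    cat_draw = rng.choice(cats, size=n3, p=[proportions[c] for c in cats])

    def magnitude() -> float:
        if effect_sigma <= 0:
            return effect_log2
        return float(effect_log2 * np.exp(rng.normal(0.0, effect_sigma)))

    truth_rows: list[dict] = []
    per_species_effect: dict[str, np.ndarray] = {
        sp: np.zeros(n_genes) for sp in species
    }
    for i in range(n3):
        cat = cat_draw[i]
        group = str(1001 + i) if len(species) >= 2 else ""
        if cat == "null":
            eff = {sp: 0.0 for sp in species}
        elif cat in ("conserved_up", "conserved_down"):
            sign = 1.0 if cat == "conserved_up" else -1.0
            eff = {sp: sign * magnitude() for sp in species}
        elif cat == "specific":
            chosen = species[int(rng.integers(len(species)))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            eff = {sp: (sign * magnitude() if sp == chosen else 0.0) for sp in species}
        else:  # divergent: one species opposes the others
            flipped = species[int(rng.integers(len(species)))]
            base_sign = 1.0 if rng.random() < 0.5 else -1.0
            eff = {
                sp: (-base_sign if sp == flipped else base_sign) * magnitude()
                for sp in species
            }
        for sp in species:
            per_species_effect[sp][i] = eff[sp]
            truth_rows.append(
                dict(
                    species=sp,
                    gene_id=gene_ids[sp][i],
                    group_id=group,
                    category=cat,
                    effect_log2=eff[sp],
                )
            )
    for sp in species:
        for i in range(n3, n_genes):
            truth_rows.append(
                dict(
                    species=sp,
                    gene_id=gene_ids[sp][i],
                    group_id=group_of.get((sp, gene_ids[sp][i]), ""),
                    category="null",
                    effect_log2=0.0,
                )
            )
    truth = ExperimentTruth(
        genes=pd.DataFrame(truth_rows), times=tuple(times)
    )

    all_values = []
    all_sheet: list[dict] = []
    gene_map_parts = []
    for sp in species:
        genes = pd.DataFrame(
            {
                "probe_id": [g + "_p1" for g in gene_ids[sp]],
                "gene_id": gene_ids[sp],
                "effect_log2": per_species_effect[sp],
            }
        )
        values, rows = _spread_conditions(
            rng, sp, genes, tuple(times), n_reps, noise_sd, dye_bias
        )
        all_values.append(values)
        all_sheet.extend(rows)
        gene_map_parts.append(genes.set_index("probe_id")["gene_id"])
    # species blocks share no probes; concat into one block-diagonal table
    values = pd.concat(all_values, axis=0)
    values = values.fillna(np.nan)
    gene_map = pd.concat(gene_map_parts)
    table = ExpressionTable(values, gene_map, "raw_two_channel")
    sheet = pd.DataFrame(all_sheet)
    return table, sheet, ortholog_table, truth


# ---------------------------------------------------------------------------
# CHX co-treatment factorial
# ---------------------------------------------------------------------------


@dataclass
class ChxTruth:
    """Planted primary/secondary classes for the CHX factorial."""

    genes: pd.DataFrame  # gene_id, class, tcdd_effect, chx_modifier

    def classes(self) -> pd.Series:
        return self.genes.set_index("gene_id")["class"]


def generate_chx_experiment(
    n_genes: int = 200,
    proportions: dict[str, float] | None = None,
    effect_log2: float = 2.0,
    noise_sd: float = 0.2,
    n_reps: int = 3,
    times: tuple[float, ...] = (4.0, 12.0),
    species: str = "mouse",
    dye_bias=default_dye_bias,
    seed: int = 0,
):
    """Simulate the 2x2 TCDD x CHX factorial design.

    Two contrasts are hybridized per time point: TCDD vs vehicle (the plain
    response, r0) and TCDD+CHX vs CHX (the response under translation
    blockade, r1), each with ``n_reps`` replicates and dye-swap labelings.
    Primary genes retain or amplify their TCDD effect under CHX
    (multiplicative modifier >= 1); secondary genes are attenuated or blocked
    (modifier 0 or 0.2); nonresponsive genes have no TCDD effect.

    Returns ``(ExpressionTable, sample_sheet, ChxTruth)``.
    """
    if proportions is None:
        proportions = {"primary": 0.15, "secondary": 0.15, "nonresponsive": 0.70}
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    classes = rng.choice(
        list(proportions), size=n_genes, p=list(proportions.values())
    )
    gene_ids = [f"{species[:2]}_chx_g{i:05d}" for i in range(n_genes)]
    tcdd_effect = np.zeros(n_genes)
    modifier = np.zeros(n_genes)
    for i, cls in enumerate(classes):
        if cls == "nonresponsive":
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        tcdd_effect[i] = sign * effect_log2
        if cls == "primary":
            modifier[i] = float(rng.choice([1.0, 1.5, 2.0]))
        else:
            modifier[i] = float(rng.choice([0.0, 0.2]))
    truth = ChxTruth(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "class": classes,
                "tcdd_effect": tcdd_effect,
                "chx_modifier": modifier,
            }
        )
    )

    all_values = []
    sheet_rows: list[dict] = []
    contrasts = [
        ("TCDD", "vehicle", tcdd_effect),
        ("TCDD+CHX", "CHX", tcdd_effect * modifier),
    ]
    for treatment, control, effects in contrasts:
        genes = pd.DataFrame(
            {
                "probe_id": [f"{g}_{treatment.replace('+', '')}_p1" for g in gene_ids],
                "gene_id": gene_ids,
                "effect_log2": effects,
            }
        )
        # distinct probe ids per contrast keep the block-concat well-formed;
        # both map to the same genes
        values, rows = _spread_conditions(
            rng,
            species,
            genes,
            tuple(times),
            n_reps,
            noise_sd,
            dye_bias,
            treatment=treatment,
            control=control,
        )
        all_values.append(values)
        sheet_rows.extend(rows)
    values = pd.concat(all_values, axis=0)
    gene_map = pd.concat(
        [
            pd.Series(
                gene_ids,
                index=[f"{g}_{t.replace('+', '')}_p1" for g in gene_ids],
            )
            for t, _, _ in contrasts
        ]
    )
    table = ExpressionTable(values, gene_map, "raw_two_channel")
    sheet = pd.DataFrame(sheet_rows)
    return table, sheet, truth


# ---------------------------------------------------------------------------
# Promoters with planted DREs
# ---------------------------------------------------------------------------

# default planted 19-mer: 7 bp flank + GCGTG core + 7 bp flank
DRE_CONSENSUS_19MER = "TCTTCTCGCGTGACTCAGC"


@dataclass
class PlantedDre:
    """Specification of one DRE to plant: TSS-relative core-center position."""

    species: str
    gene_id: str
    core_center: int
    strand: str = "+"
    seq19: str = DRE_CONSENSUS_19MER

    def __post_init__(self) -> None:
        if len(self.seq19) != 19 or self.seq19[7:12] != "GCGTG":
            raise ValueError("planted 19-mer must carry GCGTG at positions 7..11")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class PromoterTruth:
    """Planted DRE inventory; background is guaranteed core-free."""

    planted: pd.DataFrame  # species, gene_id, core_center, strand, seq19
    pair_mismatches: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species_a", "gene_a", "species_b", "gene_b", "mismatches"]
        )
    )


def mutate_19mer(
    seq19: str, n_mismatches: int, rng: np.random.Generator
) -> str:
    """Substitute ``n_mismatches`` flank positions (core positions 7..11 kept)."""
    flanks = [i for i in range(19) if not 7 <= i <= 11]
    if n_mismatches > len(flanks):
        raise ValueError("at most 14 flank mismatches are possible")
    pos = rng.choice(flanks, size=n_mismatches, replace=False)
    seq = list(seq19)
    for p in pos:
        seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(seq)


def _core_free_background(
    length: int, rng: np.random.Generator, core: str = "GCGTG"
) -> np.ndarray:
    """i.i.d. uniform sequence with every core/revcomp occurrence rejected away."""
    bases = np.array(list("ACGT"))
    seq = rng.integers(0, 4, size=length)
    patterns = {core, revcomp(core)}
    while True:
        s = "".join(bases[seq])
        hit = -1
        for pat in patterns:
            j = s.find(pat)
            if j != -1 and (hit == -1 or j < hit):
                hit = j
        if hit == -1:
            return seq
        seq[hit : hit + len(core)] = rng.integers(0, 4, size=len(core))


def generate_promoters(
    planted: list[PlantedDre],
    genes: list[tuple[str, str]] | None = None,
    upstream_bp: int = 10000,
    downstream_bp: int = 1000,
    seed: int = 0,
) -> tuple[list[PromoterRecord], PromoterTruth]:
    """Build promoter records whose only DRE cores are the planted ones.

    Each promoter spans ``[-upstream_bp, +downstream_bp]`` around its TSS.
    Background sequence is i.i.d. uniform with rejection of any window
    forming the GCGTG core on either strand, so a scanner must find exactly
    the planted sites.  Minus-strand plants insert the reverse complement of
    the given 19-mer.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    length = upstream_bp + downstream_bp + 1
    tss_index = upstream_bp
    if genes is None:
        genes = sorted({(p.species, p.gene_id) for p in planted})
    by_gene: dict[tuple[str, str], list[PlantedDre]] = {g: [] for g in genes}
    for p in planted:
        key = (p.species, p.gene_id)
        if key not in by_gene:
            raise ValueError(f"planted DRE for unknown promoter {key}")
        by_gene[key].append(p)

    records: list[PromoterRecord] = []
    truth_rows: list[dict] = []
    for (species, gene_id), plants in by_gene.items():
        spans: list[tuple[int, int]] = []
        for p in plants:
            core_start_rel = p.core_center - 2  # seq19 core occupies 7..11
            start = tss_index + core_start_rel - 7
            end = start + 19
            if not (-upstream_bp <= p.core_center <= downstream_bp):
                raise ValueError(
                    f"planted core_center {p.core_center} outside window "
                    f"[-{upstream_bp}, +{downstream_bp}]"
                )
            if start < 0 or end > length:
                raise ValueError(
                    f"planted 19-mer at core_center {p.core_center} overruns "
                    "the promoter sequence"
                )
            for s0, e0 in spans:
                if start < e0 and s0 < end:
                    raise ValueError(
                        f"planted DREs overlap in {species}|{gene_id} "
                        f"(core centers {p.core_center} vs existing span)"
                    )
            spans.append((start, end))
        for _attempt in range(200):
            seq = _core_free_background(length, rng)
            s = list("".join(bases[seq]))
            for p, (start, end) in zip(plants, spans):
                insert = p.seq19 if p.strand == "+" else revcomp(p.seq19)
                s[start:end] = list(insert)
            text = "".join(s)
            # junction check: planted insertions must not create new cores
            found = set()
            for pat in ("GCGTG", "CACGC"):
                j = text.find(pat)
                while j != -1:
                    found.add(j)
                    j = text.find(pat, j + 1)
            # map found core starts back to expected plant core starts
            ok = all(
                any(s0 <= j and j + 5 <= e0 for s0, e0 in spans) for j in found
            )
            if ok:
                break
        else:
            raise RuntimeError("could not build a core-free background")
        records.append(
            PromoterRecord(
                species=species,
                gene_id=gene_id,
                sequence=text,
                tss_index=tss_index,
                upstream_bp=upstream_bp,
                downstream_bp=downstream_bp,
            )
        )
        for p in plants:
            truth_rows.append(
                dict(
                    species=species,
                    gene_id=gene_id,
                    core_center=p.core_center,
                    strand=p.strand,
                    seq19=p.seq19,
                )
            )
    truth = PromoterTruth(
        planted=pd.DataFrame(
            truth_rows, columns=["species", "gene_id", "core_center", "strand", "seq19"]
        )
    )
    return records, truth


# ---------------------------------------------------------------------------
# DRE training sets
# ---------------------------------------------------------------------------


def generate_dre_training_set(
    consensus: str = DRE_CONSENSUS_19MER,
    substitution_rates: float | list[float] = 0.1,
    n: int = 100,
    seed: int = 0,
) -> list[str]:
    """Sample ``n`` 19-mers around a consensus with per-position substitution.

    ``substitution_rates`` may be a scalar or a length-19 vector; a
    substituted position is replaced by one of the three other bases chosen
    uniformly.  Stands in for a panel of functional DREs from which a
    position weight matrix is trained.
    """
    if n <= 0:
        raise ValueError("training set size n must be positive")
    if len(consensus) != 19:
        raise ValueError("consensus must be a 19-mer")
    rates = np.broadcast_to(np.asarray(substitution_rates, dtype=float), (19,))
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("substitution rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    seqs = []
    for _ in range(n):
        seq = list(consensus)
        flips = rng.random(19) < rates
        for i in np.nonzero(flips)[0]:
            seq[i] = others[seq[i]][rng.integers(3)]
        seqs.append("".join(seq))
    return seqs


def write_training_fasta(seqs: list[str], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">dre_{i:04d}\n{s}\n")
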