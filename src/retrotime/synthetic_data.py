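"""Seed-reproducible synthetic datasets with the study's design.

The generator emulates a Met/Cys-starvation time-course: control libraries
at 6, 30 and 120 h, starved libraries at 6, 15, 30, 72 and 120 h, one
library per time point, counts drawn from a negative binomial with
variance mu + d * mu**2 over a RepeatMasker-like subfamily taxonomy.
Planted features follow smooth archetype profiles in log2 space (the shapes
the clustered heat-profiles suggest):

    progressive_up    delta(t) = +eff * t / t_max          (starved only)
    early_up          delta(t) = +eff * exp(-((ln t - ln 15)/0.6)^2 / 2)
    late_down         delta(t) = -eff * clip((t - 72)/(t_max - 72), 0, 1)
    progressive_down  delta(t) = -eff * t / t_max

The four curves are deliberately distinct in shape (gradual vs transient vs
late-onset), so they form four separable profile clusters.

Planted features can be biased toward a repeat class (LTR for up-archetypes
and LINE for down-archetypes in the default demo), which is what the
class-enrichment stage is expected to recover.  A single "transgene"
feature rises progressively in the starved series, mimicking the integrated
reporter the study uses as an internal control.

Everything is driven by one integer seed; identical spec + seed gives
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .counting import CountsMatrix, SampleSheet
from .repeat_annotation import RepeatLocus, RepeatTaxonomy, build_taxonomy

__all__ = [
    "PlantedCluster",
    "QpcrSpec",
    "SyntheticSpec",
    "SyntheticDataset",
    "simulate_repeat_dataset",
    "simulate_qpcr",
    "simulate_gmt",
]

ARCHETYPES = ("progressive_up", "early_up", "late_down", "progressive_down")

DEFAULT_CLASS_PROPORTIONS = {
    "SINE": 0.30, "LINE": 0.30, "LTR": 0.15,
    "DNA": 0.15, "Satellite": 0.05, "Others": 0.05,
}

# families per class, loosely shaped like the RepeatMasker hierarchy
DEFAULT_FAMILIES = {
    "SINE": ["Alu", "MIR"],
    "LINE": ["L1", "L2", "CR1"],
    "LTR": ["ERV1", "ERVK", "ERVL", "ERVL-MaLR"],
    "DNA": ["hAT-Charlie", "TcMar-Tigger"],
    "Satellite": ["centr"],
    "Others": ["Simple_repeat", "tRNA"],
}


@dataclass
class PlantedCluster:
    archetype: str
    n_features: int
    max_log2_effect: float = 3.0
    class_bias: str | None = None     # e.g. "LTR"
    bias_strength: float = 0.7        # probability a planted feature takes the biased class

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")


@dataclass
class QpcrSpec:
    conditions: tuple[str, ...] = ("control", "starved_72h")
    control_condition: str = "control"
    genes: dict = field(default_factory=lambda: {"OA1": 8.0, "HDAC4": 0.25})
    reference_gene: str = "ARPC2"
    efficiencies: dict = field(default_factory=lambda: {"OA1": 1.95, "HDAC4": 1.9,
                                                        "ARPC2": 2.0})
    ct_noise_sd: float = 0.1
    n_replicates: int = 2
    ct_baseline: float = 22.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study; defaults are the demo conditions."""

    seed: int = 42
    n_subfamilies: int = 2000
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    control_times: tuple[float, ...] = (6.0, 30.0, 120.0)
    starved_times: tuple[float, ...] = (6.0, 15.0, 30.0, 72.0, 120.0)
    library_size: int = 200_000
    dispersion: float = 0.1
    mean_loci_per_subfamily: float = 8.0
    planted: list[PlantedCluster] = field(default_factory=lambda: [
        PlantedCluster("progressive_up", 25, 3.0, class_bias="LTR"),
        PlantedCluster("early_up", 25, 3.0, class_bias="LTR"),
        PlantedCluster("late_down", 25, 3.0, class_bias="LINE"),
        PlantedCluster("progressive_down", 25, 3.0, class_bias="LINE"),
    ])
    with_transgene: bool = True
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        if sum(p.n_features for p in self.planted) > self.n_subfamilies:
            raise ValueError("more planted features than subfamilies")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _profile_delta(archetype: str, t: np.ndarray, eff: float,
                   t_max: float = 120.0) -> np.ndarray:
    if archetype == "progressive_up":
        return eff * t / t_max
    if archetype == "early_up":
        return eff * np.exp(-0.5 * ((np.log(t) - np.log(15.0)) / 0.6) ** 2)
    if archetype == "late_down":
        return -eff * np.clip((t - 72.0) / (t_max - 72.0), 0.0, 1.0)
    if archetype == "progressive_down":
        return -eff * t / t_max
    raise ValueError(f"unknown archetype {archetype!r}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, d: float) -> np.ndarray:
    if d == 0:
        return rng.poisson(mu)
    theta = 1.0 / d
    return rng.negative_binomial(theta, theta / (theta + mu))


@dataclass
class SyntheticDataset:
    """In-memory bundle mirroring the files the pipeline reads."""

    loci: list[RepeatLocus]
    taxonomy: RepeatTaxonomy
    counts: CountsMatrix
    samples: SampleSheet
    truth: pd.DataFrame
    spec: SyntheticSpec

    def write(self, outdir: str | Path, reads: bool = False,
              reads_read_length: int = 50) -> dict[str, Path]:
        """Write the dataset in the dialects the pipeline consumes."""
        from .repeat_annotation import write_bed, write_taxonomy_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation_bed": outdir / "repeats.bed",
            "taxonomy": outdir / "taxonomy.tsv",
            "counts": outdir / "counts.tsv",
            "lengths": outdir / "lengths.tsv",
            "samples": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_bed(self.loci, paths["annotation_bed"])
        write_taxonomy_tsv(self.taxonomy, paths["taxonomy"])
        self.counts.to_tsv(paths["counts"], paths["lengths"])
        self.samples.to_tsv(paths["samples"])
        self.truth.to_csv(paths["truth"], sep="\t", index_label="feature")
        if reads:
            paths["reads_dir"] = outdir / "reads"
            self.write_reads(paths["reads_dir"], read_length=reads_read_length)
        return paths

    def write_reads(self, outdir: str | Path, read_length: int = 50) -> list[Path]:
        """Emit per-sample BED read files whose per-subfamily coverage counts
        reproduce the count matrix exactly (reads placed fully inside loci)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(self.spec.seed + 7919)
        by_subfamily: dict[str, list[RepeatLocus]] = {}
        for locus in self.loci:
            by_subfamily.setdefault(locus.subfamily, []).append(locus)
        paths = []
        for sample in self.counts.samples:
            path = outdir / f"{sample}.bed"
            with open(path, "w") as fh:
                rid = 0
                for feat in self.counts.features:
                    n = int(self.counts.counts.at[feat, sample])
                    if n == 0:
                        continue
                    loci = by_subfamily[feat]
                    lens = np.array([l.length for l in loci], dtype=float)
                    alloc = rng.multinomial(n, lens / lens.sum())
                    for locus, k in zip(loci, alloc):
                        span = max(1, locus.length - read_length)
                        starts = locus.start + rng.integers(0, span, size=k)
                        ends = np.minimum(starts + read_length, locus.end)
                        for s, e in zip(starts, ends):
                            fh.write(f"{locus.chrom}\t{s}\t{e}\t{sample}.r{rid}\n")
                            rid += 1
            paths.append(path)
        return paths


def _make_taxonomy_and_loci(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[str], list[str], list[str], list[RepeatLocus]]:
    classes = sorted(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in classes])
    feat_classes = [classes[i] for i in rng.choice(len(classes),
                                                   size=spec.n_subfamilies, p=probs)]
    names, families = [], []
    per_class_counter: dict[str, int] = {}
    for cls in feat_classes:
        i = per_class_counter.get(cls, 0)
        per_class_counter[cls] = i + 1
        fams = DEFAULT_FAMILIES.get(cls, [cls])
        fam = fams[i % len(fams)]
        names.append(f"{cls[:2].upper()}{fam.replace('-', '')[:4]}_{i:04d}")
        families.append(fam)

    # lay loci head-to-tail on a few synthetic chromosomes
    loci: list[RepeatLocus] = []
    n_chroms = 5
    cursors = {f"chr{i + 1}": 1000 for i in range(n_chroms)}
    for j, (name, fam, cls) in enumerate(zip(names, families, feat_classes)):
        n_loci = 1 + rng.poisson(spec.mean_loci_per_subfamily - 1)
        chrom = f"chr{(j % n_chroms) + 1}"
        for _ in range(n_loci):
            length = int(rng.integers(200, 3000))
            start = cursors[chrom]
            cursors[chrom] = start + length + int(rng.integers(50, 500))
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(RepeatLocus(chrom=chrom, start=start, end=start + length,
                                    strand=strand, subfamily=name,
                                    family=fam, class_=cls))
    return names, families, feat_classes, loci


def simulate_repeat_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate the full synthetic repeat time-course dataset."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    names, families, feat_classes, loci = _make_taxonomy_and_loci(spec, rng)
    class_arr = np.array(feat_classes)

    # assign planted archetypes, tilting toward the biased class
    archetype = np.array(["null"] * spec.n_subfamilies, dtype=object)
    effect = np.zeros(spec.n_subfamilies)
    available = np.arange(spec.n_subfamilies)
    rng.shuffle(available)
    available = list(available)
    for cluster in spec.planted:
        chosen: list[int] = []
        if cluster.class_bias is not None:
            in_class = [i for i in available if class_arr[i] == cluster.class_bias]
            n_bias = int(round(cluster.bias_strength * cluster.n_features))
            if len(in_class) < n_bias:
                raise ValueError(
                    f"cannot plant {n_bias} {cluster.class_bias} features: "
                    f"only {len(in_class)} unplanted subfamilies of that class"
                )
            chosen.extend(in_class[:n_bias])
        remaining = [i for i in available if i not in set(chosen)]
        chosen.extend(remaining[: cluster.n_features - len(chosen)])
        for i in chosen:
            archetype[i] = cluster.archetype
            effect[i] = cluster.max_log2_effect
            available.remove(i)

    # sample sheet: one library per (series, time)
    rows = []
    for t in spec.control_times:
        rows.append({"sample": f"ctrl_{int(t)}h", "series": "control", "time_h": t})
    for t in spec.starved_times:
        rows.append({"sample": f"starv_{int(t)}h", "series": "starved", "time_h": t})
    sheet = SampleSheet(pd.DataFrame(rows).set_index("sample"))

    # baseline relative abundances (log-normal), scaled to the library size
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_subfamilies)
    rel /= rel.sum()
    base_mu = rel * spec.library_size

    counts = {}
    for sample, meta in sheet.frame.iterrows():
        t, series = float(meta["time_h"]), meta["series"]
        delta = np.zeros(spec.n_subfamilies)
        if series == "starved":
            for arch in ARCHETYPES:
                mask = archetype == arch
                if mask.any():
                    unit = _profile_delta(arch, np.full(mask.sum(), t), 1.0)
                    delta[mask] = unit * effect[mask]
        mu = base_mu * 2.0 ** delta
        counts[sample] = _nb_draw(rng, mu, spec.dispersion)

    index = pd.Index(names, name="subfamily")
    count_frame = pd.DataFrame(counts, index=index)

    # subfamily lengths = summed locus lengths
    lengths = pd.Series(0, index=index, dtype=np.int64)
    for locus in loci:
        lengths[locus.subfamily] += locus.length

    truth = pd.DataFrame({
        "archetype": archetype,
        "class": feat_classes,
        "family": families,
        "max_log2_effect": effect,
    }, index=index)

    if spec.with_transgene:
        tg_name = "transgene_OA1"
        tg_mu = 200.0
        tg_counts = {}
        for sample, meta in sheet.frame.iterrows():
            t, series = float(meta["time_h"]), meta["series"]
            delta = _profile_delta("progressive_up", np.array([t]), 3.0)[0] \
                if series == "starved" else 0.0
            tg_counts[sample] = int(_nb_draw(
                rng, np.array([tg_mu * 2.0 ** delta]), spec.dispersion)[0])
        count_frame.loc[tg_name] = tg_counts
        lengths.loc[tg_name] = 1500
        truth.loc[tg_name] = {"archetype": "transgene", "class": "Others",
                              "family": "transgene", "max_log2_effect": 3.0}
        loci = loci + [RepeatLocus(chrom="chr1", start=10_000_000,
                                   end=10_001_500, strand="+",
                                   subfamily=tg_name, family="transgene",
                                   class_="Others")]

    taxonomy = build_taxonomy(loci)
    matrix = CountsMatrix(counts=count_frame, lengths=lengths, level="subfamily")
    return SyntheticDataset(loci=loci, taxonomy=taxonomy, counts=matrix,
                            samples=sheet, truth=truth, spec=spec)


def simulate_qpcr(spec: QpcrSpec | SyntheticSpec | None = None,
                  seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format Ct table plus the true fold-change table.

    Ct(sample) = Ct_baseline - log_E(relative quantity) + N(0, noise_sd);
    the reference gene's true quantity is condition-independent.
    """
    if isinstance(spec, SyntheticSpec):
        seed = spec.seed if seed is None else seed
        spec = spec.qpcr
    spec = spec or QpcrSpec()
    rng = np.random.default_rng(0 if seed is None else seed)
    for g, e in spec.efficiencies.items():
        if not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency of {g} must be in (1, 2], got {e}")

    genes = dict(spec.genes)
    genes[spec.reference_gene] = None  # flat across conditions
    rows, truth_rows = [], []
    for gene, fc in genes.items():
        e = spec.efficiencies.get(gene, 2.0)
        base = spec.ct_baseline + rng.normal(0, 2.0)
        for cond in spec.conditions:
            if gene == spec.reference_gene or cond == spec.control_condition:
                quantity = 1.0
            else:
                quantity = fc
            ct_true = base - np.log(quantity) / np.log(e)
            for rep in range(1, spec.n_replicates + 1):
                ct = ct_true + rng.normal(0, spec.ct_noise_sd)
                rows.append({"sample": f"{cond}_r{rep}", "condition": cond,
                             "gene": gene, "ct": float(ct),
                             "replicate": rep})
            if gene != spec.reference_gene:
                truth_rows.append({"gene": gene, "condition": cond,
                                   "true_fold_change": quantity})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_gmt(
    n_sets: int = 20,
    set_size: int = 50,
    n_genes: int = 2000,
    enriched_set: int = 3,
    n_list: int = 100,
    enrichment_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, set[str]], list[str], list[str]]:
    """Random gene-set collection plus a gene list enriched in one set.

    Returns (gmt mapping, gene list, background).  The list draws
    *enrichment_fraction* of its members from ``SET_{enriched_set}`` and the
    rest uniformly from the background.
    """
    if not 0 <= enriched_set < n_sets:
        raise ValueError(f"enriched_set {enriched_set} outside [0, {n_sets})")
    rng = np.random.default_rng(seed)
    background = [f"GENE{i:05d}" for i in range(n_genes)]
    sets = {
        f"SET_{k}": set(rng.choice(background, size=set_size, replace=False))
        for k in range(n_sets)
    }
    target = sorted(sets[f"SET_{enriched_set}"])
    n_from_set = int(n_list * enrichment_fraction)
    picked = list(rng.choice(target, size=min(n_from_set, len(target)),
                             replace=False))
    rest_pool = sorted(set(background) - set(picked))
    picked += list(rng.choice(rest_pool, size=n_list - len(picked), replace=False))
    return sets, picked, background


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")
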