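"""Synthetic multi-domain single-cell and spatial datasets with known ground
truth.

The count model is a gamma-mixed Poisson (negative-binomial-like) over
per-gene base abundances: each domain (tissue/slide) applies a multiplicative
log-normal shift to every gene's baseline, malignant cells multiply a shared
set of signal genes by a fold change f, and optional "shortcut" genes are
multiplied by a domain-specific fold in malignant cells of designated
training domains only — planting a label-predictive feature that does not
generalize out of domain. Per-cell library sizes vary uniformly within a
range; classes are exactly balanced per domain by construction.

Two benchmark presets mirror the study design at desk scale (5 training
domains, one extra-domain validation set for checkpoint selection, one
held-out test domain sharing the signal): ``separable`` (strong clean
signal) and ``shortcut`` (weaker signal plus a domain-confounded shortcut of
heterogeneous strength, the construction under which the variance-of-risks
penalty is expected to help).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import LAYER_RAW, AnnotationTable, ExpressionMatrix


@dataclass
class SimConfig:
    """Generator parameters. ``cells_per_domain`` is the total per domain and
    is split equally between the classes. ``spurious_folds`` gives the
    malignant-cell multiplier of the shortcut genes per domain (1.0 =
    inactive in that domain); an empty list disables shortcuts."""

    n_domains: int = 5
    cells_per_domain: int = 200
    n_genes: int = 500
    n_signal_genes: int = 20
    fold_change: float = 6.0
    domain_effect_sigma: float = 0.2
    n_spurious_genes: int = 0
    spurious_folds: list[float] = field(default_factory=list)
    dispersion: float = 10.0  # gamma shape; variance = mu + mu^2/dispersion
    library_size_range: tuple[int, int] = (5000, 10000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.cells_per_domain < 2 or self.cells_per_domain % 2:
            raise ValueError("cells_per_domain must be an even number >= 2")
        if self.n_signal_genes + self.n_spurious_genes > self.n_genes:
            raise ValueError("signal and shortcut gene sets exceed n_genes")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")
        if self.spurious_folds and len(self.spurious_folds) != self.n_domains:
            raise ValueError("spurious_folds must list one fold per domain")
        if self.n_spurious_genes and not self.spurious_folds:
            raise ValueError("spurious genes configured without per-domain folds")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_size_range")


@dataclass
class GroundTruth:
    """What the generator planted: gene names of the malignancy signal and of
    the domain-confounded shortcut, plus the full configuration."""

    signal_genes: list[str]
    spurious_genes: list[str]
    config: SimConfig

    def to_json(self, path) -> None:
        payload = {
            "signal_genes": self.signal_genes,
            "spurious_genes": self.spurious_genes,
            "config": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in self.config.__dict__.items()
                }
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _gene_names(n: int) -> list[str]:
    return [f"G{j:04d}" for j in range(n)]


def _sample_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.float64)


def generate_multidomain(
    cfg: SimConfig, domain_prefix: str = "domain"
) -> tuple[ExpressionMatrix, AnnotationTable, GroundTruth]:
    """Generate balanced multi-domain raw counts with a shared malignancy
    signal and optional per-domain shortcut genes. Fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    # plant signal/shortcut effects only in expressed genes (baseline at or
    # above the median abundance) — a fold change on a silent gene plants no
    # recoverable signal
    eligible = np.flatnonzero(base >= np.median(base))
    picked = rng.choice(
        eligible, cfg.n_signal_genes + cfg.n_spurious_genes, replace=False
    )
    signal_ix = np.sort(picked[: cfg.n_signal_genes])
    spurious_ix = np.sort(picked[cfg.n_signal_genes:])
    per_class = cfg.cells_per_domain // 2
    lo, hi = cfg.library_size_range

    values = []
    cell_ids: list[str] = []
    labels: list[int] = []
    domains: list[str] = []
    for d in range(cfg.n_domains):
        dname = f"{domain_prefix}_{d}"
        shift = rng.lognormal(mean=0.0, sigma=cfg.domain_effect_sigma, size=cfg.n_genes)
        sp_fold = cfg.spurious_folds[d] if cfg.spurious_folds else 1.0
        for label in (1, 0):
            w = base * shift
            if label == 1:
                w = w.copy()
                w[signal_ix] *= cfg.fold_change
                if len(spurious_ix):
                    w[spurious_ix] *= sp_fold
            p = w / w.sum()
            lib = rng.uniform(lo, hi, size=per_class)
            mean = lib[:, None] * p[None, :]
            values.append(_sample_counts(rng, mean, cfg.dispersion))
            for i in range(per_class):
                cell_ids.append(f"{dname}_c{label}_{i}")
                labels.append(label)
                domains.append(dname)

    matrix = ExpressionMatrix(np.vstack(values), cell_ids, genes, LAYER_RAW)
    ann = AnnotationTable(cell_ids, np.array(labels), domains)
    truth = GroundTruth(
        signal_genes=[genes[j] for j in signal_ix],
        spurious_genes=[genes[j] for j in spurious_ix],
        config=cfg,
    )
    return matrix, ann, truth


# ---------------------------------------------------------------------------
# spatial grids
# ---------------------------------------------------------------------------

def interface_mask(tumor_region: np.ndarray) -> np.ndarray:
    """Boundary of the tumor mask: tumor spots with at least one 4-neighbor
    outside the tumor region (grid edges do not count as outside)."""
    mask = np.asarray(tumor_region, dtype=bool)
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def generate_spatial_grid(
    cfg: SimConfig,
    grid: tuple[int, int],
    tumor_region: np.ndarray,
    slide_id: str = "slide_0",
    noise_seed: int | None = None,
) -> tuple[ExpressionMatrix, AnnotationTable, GroundTruth, np.ndarray]:
    """Generate one spatial slide: spots on a rows x cols grid, spots inside
    ``tumor_region`` labeled 1 with elevated signal-gene expression, domain =
    slide id. Returns (counts, annotations-with-coordinates, ground truth,
    per-spot interface flag for tumor-boundary spots).

    ``cfg.seed`` fixes the gene baseline and the signal-gene set;
    ``noise_seed`` (default: cfg.seed) drives the slide-specific domain
    shift, library sizes, and counts — so multiple slides generated with the
    same cfg but different noise seeds share one malignancy signal, the way
    slides of one cancer type share biology but differ technically."""
    rows, cols = grid
    mask = np.asarray(tumor_region, dtype=bool)
    if mask.shape != (rows, cols):
        raise ValueError("tumor_region shape does not match the grid")
    if not mask.any():
        raise ValueError("tumor region is empty")

    rng_shared = np.random.default_rng(cfg.seed)
    rng = np.random.default_rng(cfg.seed if noise_seed is None else noise_seed)
    genes = _gene_names(cfg.n_genes)
    base = rng_shared.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    eligible = np.flatnonzero(base >= np.median(base))
    signal_ix = np.sort(rng_shared.choice(eligible, cfg.n_signal_genes, replace=False))
    shift = rng.lognormal(mean=0.0, sigma=cfg.domain_effect_sigma, size=cfg.n_genes)
    lo, hi = cfg.library_size_range

    w_normal = base * shift
    w_tumor = w_normal.copy()
    w_tumor[signal_ix] *= cfg.fold_change
    p_normal = w_normal / w_normal.sum()
    p_tumor = w_tumor / w_tumor.sum()

    n_spots = rows * cols
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    labels = mask.reshape(-1).astype(np.int64)
    lib = rng.uniform(lo, hi, size=n_spots)
    p = np.where(labels[:, None] == 1, p_tumor[None, :], p_normal[None, :])
    counts = _sample_counts(rng, lib[:, None] * p, cfg.dispersion)

    spot_ids = [f"{slide_id}_r{int(r)}_c{int(c)}" for r, c in coords]
    matrix = ExpressionMatrix(counts, spot_ids, genes, LAYER_RAW)
    ann = AnnotationTable(spot_ids, labels, [slide_id] * n_spots, coords)
    truth = GroundTruth(
        signal_genes=[genes[j] for j in signal_ix], spurious_genes=[], config=cfg
    )
    return matrix, ann, truth, interface_mask(mask).reshape(-1)


# ---------------------------------------------------------------------------
# benchmark presets: 5 train domains + extra-domain validation + held-out test
# ---------------------------------------------------------------------------

N_TRAIN_DOMAINS = 5

#: per-training-domain malignant-cell fold of the shortcut genes (heterogeneous
#: so a shortcut-reliant model has unequal per-domain risks); the validation
#: and test domains get fold 1.0 (shortcut uninformative out of domain)
SHORTCUT_TRAIN_FOLDS = [12.0, 10.0, 8.0, 6.0, 4.0]


@dataclass
class Benchmark:
    train_matrix: ExpressionMatrix
    train_ann: AnnotationTable
    extra_matrix: ExpressionMatrix
    extra_labels: np.ndarray
    test_matrix: ExpressionMatrix
    test_labels: np.ndarray
    truth: GroundTruth


def make_benchmark(kind: str, seed: int) -> Benchmark:
    """Build a train / extra-domain-validation / held-out-test benchmark.

    ``separable``: 5 training domains, 200 cells each, 500 genes, 20 signal
    genes at fold 6, no shortcuts. ``shortcut``: the same plus 10 shortcut
    genes active (with heterogeneous strength) only in the training domains.
    Both add one validation and one test domain drawn from the same signal
    but free of shortcuts.
    """
    if kind == "separable":
        cfg = SimConfig(n_domains=N_TRAIN_DOMAINS + 2, seed=seed)
    elif kind == "shortcut":
        # identical to "separable" except for the planted shortcut, so the
        # paired comparison manipulates exactly one variable
        cfg = SimConfig(
            n_domains=N_TRAIN_DOMAINS + 2,
            n_spurious_genes=10,
            spurious_folds=SHORTCUT_TRAIN_FOLDS + [1.0, 1.0],
            seed=seed,
        )
    else:
        raise ValueError(f"unknown benchmark kind {kind!r}")

    matrix, ann, truth = generate_multidomain(cfg)
    names = ann.domain_names
    train_names = set(names[:N_TRAIN_DOMAINS])
    extra_name, test_name = names[N_TRAIN_DOMAINS], names[N_TRAIN_DOMAINS + 1]

    def rows(pred):
        return [i for i, d in enumerate(ann.domains) if pred(d)]

    tr = rows(lambda d: d in train_names)
    ex = rows(lambda d: d == extra_name)
    te = rows(lambda d: d == test_name)
    return Benchmark(
        train_matrix=matrix.subset_cells(tr),
        train_ann=ann.subset(tr),
        extra_matrix=matrix.subset_cells(ex),
        extra_labels=ann.labels[ex],
        test_matrix=matrix.subset_cells(te),
        test_labels=ann.labels[te],
        truth=truth,
    )


def run_benchmark(
    bench: Benchmark,
    beta: float,
    seed: int,
    n_hvgs: int = 200,
    learning_rate: float = 1e-3,
    batch_per_domain: int = 64,
    max_epochs: int = 30,
    bottleneck_dim: int = 512,
):
    """Train on the benchmark's training domains (full pipeline: normalize,
    balance, split, HVG selection, VREx training with extra-domain checkpoint
    selection) and score the held-out test domain.

    Returns a dict with the checkpoint model, selected features, trace, and
    held-out accuracy.
    """
    from .model import predict
    from .preprocessing import PreprocessConfig, align_features, normalize_cells
    from .training import TrainConfig, fit_malignancy_model

    pre_cfg = PreprocessConfig(n_hvgs=n_hvgs, seed=seed)
    train_cfg = TrainConfig(
        beta=beta,
        learning_rate=learning_rate,
        batch_per_domain=batch_per_domain,
        max_epochs=max_epochs,
        seed=seed,
    )
    model, trace, info = fit_malignancy_model(
        bench.train_matrix,
        bench.train_ann,
        pre_cfg=pre_cfg,
        train_cfg=train_cfg,
        extra_raw=bench.extra_matrix,
        extra_labels=bench.extra_labels,
        bottleneck_dim=bottleneck_dim,
    )
    test_norm = normalize_cells(bench.test_matrix, pre_cfg.scale_factor)
    test_aligned, _ = align_features(test_norm, model.feature_list)
    _, _, calls = predict(model, test_aligned.values)
    heldout = float(np.mean(calls == bench.test_labels))
    return {
        "model": model,
        "trace": trace,
        "info": info,
        "heldout_accuracy": heldout,
    }


# ---------------------------------------------------------------------------
# shortcut-construction verification
# ---------------------------------------------------------------------------

def best_threshold_accuracy(x_train, y_train, x_test, y_test):
    """Fit a single-feature threshold classifier (best cut and direction on
    the training values) and report (train accuracy, test accuracy)."""
    x_train = np.asarray(x_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    cuts = np.unique(x_train)
    mids = np.concatenate(([cuts[0] - 1.0], (cuts[:-1] + cuts[1:]) / 2.0, [cuts[-1] + 1.0]))
    best = (-1.0, 0.0, 1)
    for direction in (1, -1):
        pred = (x_train[None, :] > mids[:, None]) if direction == 1 else (
            x_train[None, :] <= mids[:, None]
        )
        acc = (pred == (y_train[None, :] == 1)).mean(axis=1)
        j = int(np.argmax(acc))
        if acc[j] > best[0]:
            best = (float(acc[j]), float(mids[j]), direction)
    train_acc, cut, direction = best
    x_test = np.asarray(x_test, dtype=np.float64)
    y_test = np.asarray(y_test, dtype=np.int64)
    pred_test = (x_test > cut) if direction == 1 else (x_test <= cut)
    return train_acc, float((pred_test == (y_test == 1)).mean())


def shortcut_construction_check(bench: Benchmark) -> dict[str, float]:
    """Verify the planted shortcut: the best single shortcut-gene threshold
    classifier should be strongly predictive on the pooled training domains
    but near chance on the held-out test domain. Values are computed on
    log-normalized expression."""
    from .preprocessing import normalize_cells

    if not bench.truth.spurious_genes:
        raise ValueError("benchmark has no shortcut genes to check")
    train_norm = normalize_cells(bench.train_matrix)
    test_norm = normalize_cells(bench.test_matrix)
    col_tr = {g: j for j, g in enumerate(train_norm.gene_ids)}
    col_te = {g: j for j, g in enumerate(test_norm.gene_ids)}
    best_gene, best_train, paired_test = None, -1.0, 0.0
    for gene in bench.truth.spurious_genes:
        tr_acc, te_acc = best_threshold_accuracy(
            train_norm.values[:, col_tr[gene]],
            bench.train_ann.labels,
            test_norm.values[:, col_te[gene]],
            bench.test_labels,
        )
        if tr_acc > best_train:
            best_gene, best_train, paired_test = gene, tr_acc, te_acc
    return {
        "gene": best_gene,
        "in_train_accuracy": best_train,
        "out_of_domain_accuracy": paired_test,
    }
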