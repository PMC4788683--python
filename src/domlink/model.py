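"""Cross-validated training of window classifiers and residue prediction.

The modelling surface follows the Model/Results idiom: a
:class:`DomainLinkerModel` is built from proteins with ground-truth
annotations (plus optional disorder tracks), and :meth:`DomainLinkerModel.fit`
runs protein-level k-fold cross-validation — every window of a protein shares
that protein's fold, so overlapping windows can never leak between training
and test — training one classifier per fold. The returned
:class:`DomainLinkerResults` carries the fold models, their held-out fold
metrics, a ``summary()`` table, consensus prediction, dataset evaluation, and
(de)serialization.

Six classifier families are supported, all delegated to scikit-learn:
decision tree (DT), Gaussian naive Bayes (GNB), linear discriminant analysis
(LDA), support vector machine with an RBF kernel (SVM), random forest (RF)
and a single-hidden-layer multilayer perceptron (MLP). Hyperparameters
default to the library's documented defaults except where the method fixes
them (SVM kernel, MLP depth); every effective hyperparameter is recorded in
the model manifest so a saved model can be audited and can never be silently
paired with a mismatched encoder.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import consensus as _consensus
from .annotations import (
    LABEL_UNKNOWN,
    DisorderTrack,
    ProteinRecord,
    ResidueAnnotation,
)
from .errors import ConfigError, LengthMismatchError, ManifestError
from .features import WindowConfig, encode_matrix
from .metrics import DatasetEvaluation, MetricReport, confusion, evaluate_dataset, scores
from .scales import AAScale

logger = logging.getLogger(__name__)

FAMILIES = ("DT", "GNB", "LDA", "SVM", "RF", "MLP")

_MANIFEST_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the six classifier families plus hyperparameters and a seed."""

    family: str = "RF"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown classifier family {self.family!r}; "
                              f"expected one of {FAMILIES}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))

    def build(self):
        """Instantiate the scikit-learn estimator for this spec."""
        hp = dict(self.hyperparameters)
        if self.family == "DT":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        if self.family == "GNB":
            return GaussianNB(**hp)
        if self.family == "LDA":
            return LinearDiscriminantAnalysis(**hp)
        if self.family == "SVM":
            hp.setdefault("kernel", "rbf")
            return SVC(random_state=self.seed, **hp)
        if self.family == "RF":
            return RandomForestClassifier(random_state=self.seed, n_jobs=1, **hp)
        # MLP: one hidden layer; unit count configurable via hidden_units
        units = hp.pop("hidden_units", 100)
        hp.setdefault("max_iter", 300)
        return MLPClassifier(
            hidden_layer_sizes=(int(units),), random_state=self.seed, **hp
        )

    def effective_hyperparameters(self) -> dict:
        """The estimator's full parameter dict (library defaults resolved)."""
        params = self.build().get_params()
        return {k: v for k, v in params.items() if _json_safe(v)}


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


@dataclass(frozen=True)
class FoldAssignment:
    """Protein-level partition into folds; sizes differ by at most one."""

    n_folds: int
    fold_of: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fold_of", dict(self.fold_of))
        sizes = self.fold_sizes()
        if len(sizes) != self.n_folds or max(sizes) - min(sizes) > 1:
            raise ConfigError(f"unbalanced fold sizes {sizes}")

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.fold_of.values():
            sizes[f] += 1
        return sizes

    def test_ids(self, fold: int) -> list[str]:
        return sorted(pid for pid, f in self.fold_of.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(pid for pid, f in self.fold_of.items() if f != fold)

    def digest(self) -> str:
        payload = json.dumps(sorted(self.fold_of.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def split_folds(
    proteins: Sequence[ProteinRecord], n_folds: int = 3, seed: int = 0
) -> FoldAssignment:
    """Deterministic seeded protein-level partition into near-equal folds."""
    if n_folds < 2:
        raise ConfigError(f"n_folds must be >= 2, got {n_folds}")
    ids = sorted(p.id for p in proteins)
    if len(ids) < n_folds:
        raise ConfigError(f"{len(ids)} proteins cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = {ids[j]: int(i % n_folds) for i, j in enumerate(order)}
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of)


@dataclass
class TrainedModelSet:
    """N fold-trained classifiers of one family plus prediction metadata."""

    spec: ClassifierSpec
    models: list
    window: WindowConfig
    folds: FoldAssignment
    fold_reports: list[MetricReport]

    @property
    def channels(self) -> tuple[str, ...]:
        return self.window.channels

    def predict_residues(
        self,
        index: int,
        protein: ProteinRecord,
        disorder: DisorderTrack | None = None,
    ) -> tuple[ResidueAnnotation, np.ndarray]:
        """Per-residue prediction of one fold model.

        Returns the length-L annotation (U at the (w-1)/2 terminal residues
        on each side, where no window fits) and the matching length-L vote
        vector over {1, 0, -1}.
        """
        X, centers = encode_matrix(protein, self.window, disorder)
        votes = np.full(protein.length, _consensus.VOTE_ABSTAIN, dtype=int)
        if X.shape[0] > 0:
            pred = np.asarray(self.models[index].predict(X), dtype=int)
            votes[centers - 1] = pred
        labels = np.where(
            votes == _consensus.VOTE_ABSTAIN,
            LABEL_UNKNOWN,
            np.where(votes == _consensus.VOTE_POSITIVE, "D", "L"),
        )
        return ResidueAnnotation("".join(labels)), votes

    def predict(
        self,
        protein: ProteinRecord,
        disorder: DisorderTrack | None = None,
        n: int = 2,
    ) -> ResidueAnnotation:
        """n-star consensus prediction across the fold models."""
        return _consensus.consensus_predict(self, protein, disorder, n=n)

    def vote_matrix(
        self, protein: ProteinRecord, disorder: DisorderTrack | None = None
    ) -> np.ndarray:
        return _consensus.vote_matrix(self, protein, disorder)

    # -- serialization ------------------------------------------------------

    def manifest(self) -> dict:
        return {
            "format_version": _MANIFEST_VERSION,
            "family": self.spec.family,
            "hyperparameters": dict(self.spec.hyperparameters),
            "effective_hyperparameters": self.spec.effective_hyperparameters(),
            "seed": self.spec.seed,
            "window_width": self.window.width,
            "channels": list(self.channels),
            "feature_ordering": "residue-major",
            "scales": [
                {"accession": s.accession, "values": s.values} for s in self.window.scales
            ],
            "use_disorder": self.window.use_disorder,
            "n_folds": self.folds.n_folds,
            "fold_of": dict(self.folds.fold_of),
            "fold_assignment_digest": self.folds.digest(),
            "fold_reports": [rep.as_dict() for rep in self.fold_reports],
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
        for j, model in enumerate(self.models):
            joblib.dump(model, directory / f"model_fold{j}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModelSet":
        directory = Path(directory)
        try:
            with open(directory / "manifest.json") as fh:
                manifest = json.load(fh)
        except FileNotFoundError as exc:
            raise ManifestError(f"no manifest.json in {directory}") from exc
        if manifest.get("format_version") != _MANIFEST_VERSION:
            raise ManifestError(
                f"unsupported manifest format {manifest.get('format_version')!r}"
            )
        scales = tuple(
            AAScale(entry["accession"], entry["values"]) for entry in manifest["scales"]
        )
        window = WindowConfig(
            width=manifest["window_width"],
            scales=scales,
            use_disorder=manifest["use_disorder"],
        )
        spec = ClassifierSpec(
            family=manifest["family"],
            hyperparameters=manifest["hyperparameters"],
            seed=manifest["seed"],
        )
        folds = FoldAssignment(manifest["n_folds"], manifest["fold_of"])
        models = []
        for j in range(folds.n_folds):
            blob = directory / f"model_fold{j}.joblib"
            if not blob.exists():
                raise ManifestError(f"missing model blob {blob}")
            models.append(joblib.load(blob))
        from .metrics import ConfusionCounts

        reports = [
            MetricReport(
                accuracy=rep["accuracy"],
                recall=rep["recall"],
                precision=rep["precision"],
                f_measure=rep["f_measure"],
                counts=ConfusionCounts(
                    rep["tp"], rep["fp"], rep["tn"], rep["fn"], rep["excluded"]
                ),
                undefined=frozenset(rep["undefined"]),
            )
            for rep in manifest["fold_reports"]
        ]
        return cls(spec=spec, models=models, window=window, folds=folds,
                   fold_reports=reports)

    def check_compatible(self, window: WindowConfig) -> None:
        """Hard failure when an encoder config does not match the manifest."""
        if window.width != self.window.width:
            raise ManifestError(
                f"model was trained with window width {self.window.width}, "
                f"requested {window.width}"
            )
        if window.channels != self.channels:
            raise ManifestError(
                f"model channels {self.channels} != requested {window.channels}"
            )


class DomainLinkerModel:
    """Residue-level domain/linker classifier built from an annotated corpus.

    Parameters
    ----------
    proteins : sequence of ProteinRecord
    annotations : mapping id -> ResidueAnnotation
        Ground truth; D residues are the positive class.
    disorder : mapping id -> DisorderTrack, optional
        Predicted-disorder tracks from an external tool. When omitted the
        disorder channel is dropped from the encoding (and recorded so in the
        manifest); when given, every protein must have a track.
    spec : ClassifierSpec
    window : WindowConfig, optional
        Defaults to width 17 with the four vendored scales; the disorder
        channel is switched on iff tracks are supplied.
    n_folds : int
    seed : int
        Drives the fold split and any estimator randomness.
    undersample : bool
        Optionally balance classes by seeded undersampling of the majority
        windows in each training set (off by default: training follows the
        skewed natural distribution).
    """

    def __init__(
        self,
        proteins: Sequence[ProteinRecord],
        annotations: Mapping[str, ResidueAnnotation],
        *,
        disorder: Mapping[str, DisorderTrack] | None = None,
        spec: ClassifierSpec | None = None,
        window: WindowConfig | None = None,
        n_folds: int = 3,
        seed: int = 0,
        undersample: bool = False,
    ) -> None:
        self.proteins = list(proteins)
        self.annotations = dict(annotations)
        self.disorder = dict(disorder) if disorder is not None else None
        self.spec = spec if spec is not None else ClassifierSpec(seed=seed)
        if window is None:
            window = WindowConfig(use_disorder=self.disorder is not None)
        if window.use_disorder and self.disorder is None:
            raise ConfigError("window config enables disorder but no tracks given")
        self.window = window
        self.n_folds = n_folds
        self.seed = seed
        self.undersample = undersample
        for p in self.proteins:
            if p.id not in self.annotations:
                raise ConfigError(f"no annotation for protein {p.id!r}")
            if len(self.annotations[p.id]) != p.length:
                raise LengthMismatchError(
                    f"annotation for {p.id!r} has length "
                    f"{len(self.annotations[p.id])}, sequence {p.length}"
                )
            if self.disorder is not None and p.id not in self.disorder:
                raise ConfigError(f"no disorder track for protein {p.id!r}")

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        annotations_tsv: str | Path,
        disorder_tsv: str | Path | None = None,
        **kwargs,
    ) -> "DomainLinkerModel":
        from .annotations import parse_fasta, read_annotations, read_disorder

        proteins = parse_fasta(fasta)
        by_id = {p.id: p for p in proteins}
        annotations = read_annotations(annotations_tsv, sequences=by_id)
        disorder = read_disorder(disorder_tsv, sequences=by_id) if disorder_tsv else None
        return cls(proteins, annotations, disorder=disorder, **kwargs)

    def _track(self, pid: str) -> DisorderTrack | None:
        return self.disorder.get(pid) if self.disorder is not None else None

    def _encode_protein(self, protein: ProteinRecord):
        ann = self.annotations[protein.id]
        X, centers = encode_matrix(protein, self.window, self._track(protein.id))
        if X.shape[0] == 0:
            return X, np.empty(0, dtype=int)
        labels = np.frombuffer(ann.labels.encode(), dtype="S1")[centers - 1] == b"D"
        return X, labels.astype(int)

    def fit(self, folds: FoldAssignment | None = None) -> "DomainLinkerResults":
        """Train one classifier per fold and evaluate it on its held-out fold."""
        if folds is None:
            folds = split_folds(self.proteins, self.n_folds, self.seed)
        by_id = {p.id: p for p in self.proteins}
        encoded = {}
        for p in self.proteins:
            X, y = self._encode_protein(p)
            if X.shape[0] == 0:
                logger.warning("protein %s yields no windows; skipped", p.id)
            encoded[p.id] = (X, y)

        models = []
        fold_reports = []
        for j in range(folds.n_folds):
            train_ids = [pid for pid in folds.train_ids(j) if encoded[pid][0].shape[0]]
            X_train = np.vstack([encoded[pid][0] for pid in train_ids])
            y_train = np.concatenate([encoded[pid][1] for pid in train_ids])
            if self.undersample:
                X_train, y_train = _undersample(X_train, y_train, self.seed + j)
            if len(np.unique(y_train)) < 2:
                raise ConfigError(
                    f"fold {j}: training windows contain a single class only"
                )
            clf = self.spec.build()
            clf.fit(X_train, y_train)
            models.append(clf)

        model_set = TrainedModelSet(
            spec=self.spec, models=models, window=self.window, folds=folds,
            fold_reports=[],
        )
        for j in range(folds.n_folds):
            counts_sum = None
            for pid in folds.test_ids(j):
                pred, _ = model_set.predict_residues(j, by_id[pid], self._track(pid))
                counts = confusion(pred, self.annotations[pid])
                counts_sum = counts if counts_sum is None else counts_sum + counts
            if counts_sum is None:
                from .metrics import ConfusionCounts

                counts_sum = ConfusionCounts()
            report = scores(counts_sum)
            if report.undefined:
                logger.warning(
                    "fold %d test metrics undefined: %s", j, sorted(report.undefined)
                )
            fold_reports.append(report)
        model_set.fold_reports = fold_reports
        return DomainLinkerResults(model=self, model_set=model_set)


def _undersample(X: np.ndarray, y: np.ndarray, seed: int):
    rng = np.random.default_rng(seed)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0 or n_pos == n_neg:
        return X, y
    majority = 1 if n_pos > n_neg else 0
    keep = min(n_pos, n_neg)
    maj_idx = np.flatnonzero(y == majority)
    min_idx = np.flatnonzero(y != majority)
    chosen = np.sort(np.concatenate([min_idx, rng.choice(maj_idx, keep, replace=False)]))
    return X[chosen], y[chosen]


class DomainLinkerResults:
    """Fit results: fold models, fold metrics, prediction and evaluation."""

    def __init__(self, model: DomainLinkerModel | None, model_set: TrainedModelSet):
        self.model = model
        self.model_set = model_set

    @property
    def fold_reports(self) -> list[MetricReport]:
        return self.model_set.fold_reports

    @property
    def n_models(self) -> int:
        return len(self.model_set.models)

    def predict_residues(self, index, protein, disorder=None):
        return self.model_set.predict_residues(index, protein, disorder)

    def predict(self, protein, disorder=None, n: int = 2) -> ResidueAnnotation:
        return self.model_set.predict(protein, disorder, n=n)

    def vote_matrix(self, protein, disorder=None) -> np.ndarray:
        return self.model_set.vote_matrix(protein, disorder)

    def evaluate(
        self,
        proteins: Sequence[ProteinRecord],
        truths: Mapping[str, ResidueAnnotation],
        disorder: Mapping[str, DisorderTrack] | None = None,
        n: int = 2,
    ) -> DatasetEvaluation:
        """n-star consensus evaluation on an independent protein set."""
        predictions = {}
        for p in proteins:
            track = disorder.get(p.id) if disorder is not None else None
            predictions[p.id] = self.predict(p, track, n=n)
        return evaluate_dataset(predictions, {p.id: truths[p.id] for p in proteins})

    def summary(self) -> str:
        """Plain-text table of per-fold held-out metrics."""
        spec = self.model_set.spec
        lines = [
            "Domain/linker residue classifier — cross-validation results",
            f"family: {spec.family}   folds: {self.model_set.folds.n_folds}   "
            f"window: {self.model_set.window.width}   "
            f"channels: {', '.join(self.model_set.channels)}",
            f"seed: {spec.seed}   fold digest: {self.model_set.folds.digest()}",
            "",
            f"{'fold':>4} {'accuracy':>9} {'recall':>9} {'precision':>9} "
            f"{'F-measure':>9} {'TP':>8} {'FP':>7} {'TN':>7} {'FN':>7}",
        ]

        def fmt(v):
            return f"{v:9.4f}" if v is not None else f"{'undef':>9}"

        for j, rep in enumerate(self.fold_reports):
            c = rep.counts
            lines.append(
                f"{j:>4} {fmt(rep.accuracy)} {fmt(rep.recall)} {fmt(rep.precision)} "
                f"{fmt(rep.f_measure)} {c.tp:>8} {c.fp:>7} {c.tn:>7} {c.fn:>7}"
            )
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        self.model_set.save(directory)

    @classmethod
    def load(cls, directory: str | Path) -> "DomainLinkerResults":
        return cls(model=None, model_set=TrainedModelSet.load(directory))
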