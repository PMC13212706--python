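"""Mean-teacher training mechanics for partially labeled lesion segmentation.

Two copies of the same 3D U-Net are maintained: a *student* trained by
backpropagation and a *teacher* whose weights are an exponential moving
average (EMA) of the student's.  Every case — expert-annotated,
pseudo-annotated, unannotated-positive or negative — passes through both
branches: the student sees the (noise-augmented) volume, the teacher sees a
randomly drawn invertible spatial transform of it, and the teacher's output
is mapped back through the inverse transform before a voxel-wise consistency
penalty is applied.  Only cases with a usable mask (expert, pseudo, or the
implicit all-background mask of negatives) additionally contribute the
supervised focal + Dice term.

Pseudo-labeling is two-stage and frozen: a supervised model is trained
first, its probability maps on the report-positive unannotated cases are
post-processed by the lesion-candidate extractor, and the retained
candidates become fixed pseudo masks for the semi-supervised run.

The trainer is a scikit-learn style estimator
(:class:`MeanTeacherSegmenter`): ``fit`` takes a list of
:class:`~lesionssl.phantom.AnnotatedCase`, ``predict_proba`` returns
foreground probability maps, and the fitted state lives in ``state_`` /
``history_``.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from . import losses
from .nn import Adam, SegmentationNetworkSpec, UNet3D
from .phantom import AnnotatedCase
from .transforms import sample_transform

log = logging.getLogger("lesionssl")


@dataclass
class TeacherStudentState:
    """Student/teacher parameter trees coupled by EMA decay ``alpha``."""

    student: dict
    teacher: dict
    ema_decay: float
    step: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ValueError("ema_decay must be in [0, 1]")
        if set(self.student) != set(self.teacher):
            raise ValueError("student and teacher parameter trees differ structurally")


def ema_update(state: TeacherStudentState) -> TeacherStudentState:
    """One EMA step: teacher <- alpha * teacher + (1 - alpha) * student.

    The student is untouched; the step counter increments.  Shapes are
    checked leaf by leaf.
    """
    a = state.ema_decay
    new_teacher = {}
    for k, t in state.teacher.items():
        s = state.student[k]
        if s.shape != t.shape:
            raise ValueError(f"parameter {k!r}: student shape {s.shape} != teacher {t.shape}")
        new_teacher[k] = (a * t + (1.0 - a) * s).astype(t.dtype)
    return TeacherStudentState(student=state.student, teacher=new_teacher,
                               ema_decay=a, step=state.step + 1)


class MeanTeacherSegmenter(BaseEstimator):
    """Semi-supervised mean-teacher 3D lesion segmenter.

    Parameters
    ----------
    depth, base_width, convs_per_block, norm
        Backbone configuration (see :class:`SegmentationNetworkSpec`).
    epochs, batch_size, learning_rate
        Adam optimisation schedule over whole volumes.
    ema_decay
        Teacher EMA decay ``alpha`` in [0, 1).
    lambda_max, ramp_fraction
        Consistency weight schedule: a sigmoid-shaped ramp from 0 to
        ``lambda_max`` over the first ``ramp_fraction`` of steps.
    focal_gamma, lesion_class_weight, focal_weight, dice_weight
        Supervised loss composition.
    noise_aug_sd
        SD of the student-/teacher-side additive intensity noise (applied
        before the teacher's spatial transform; intensity augmentation needs
        no inverse so it is not part of the reversible transform).
    allowed_primitives, max_translation
        Family of invertible transforms sampled for the teacher branch.
    use_teacher_for_inference
        Predict with the EMA teacher (default) or the raw student.
    random_state
        Seeds initialisation, data order, transform sampling and noise, each
        from an independent stream; identical seeds give bit-identical runs.
    """

    def __init__(self, depth=3, base_width=4, convs_per_block=1, norm="instance",
                 epochs=30, batch_size=8, learning_rate=1e-2, ema_decay=0.95,
                 lambda_max=1.0, ramp_fraction=0.4, focal_gamma=2.0,
                 lesion_class_weight=1.0, focal_weight=1.0, dice_weight=1.0,
                 noise_aug_sd=0.05, allowed_primitives=("flip", "rot90", "translate"),
                 max_translation=2, use_teacher_for_inference=True,
                 random_state=None, verbose=0):
        self.depth = depth
        self.base_width = base_width
        self.convs_per_block = convs_per_block
        self.norm = norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.ema_decay = ema_decay
        self.lambda_max = lambda_max
        self.ramp_fraction = ramp_fraction
        self.focal_gamma = focal_gamma
        self.lesion_class_weight = lesion_class_weight
        self.focal_weight = focal_weight
        self.dice_weight = dice_weight
        self.noise_aug_sd = noise_aug_sd
        self.allowed_primitives = allowed_primitives
        self.max_translation = max_translation
        self.use_teacher_for_inference = use_teacher_for_inference
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ----------------------------------------------------------

    def _spec(self) -> SegmentationNetworkSpec:
        return SegmentationNetworkSpec(depth=self.depth, base_width=self.base_width,
                                       convs_per_block=self.convs_per_block,
                                       norm=self.norm)

    @staticmethod
    def _validate_cases(cases) -> tuple:
        if not cases:
            raise ValueError("empty training view")
        grid = cases[0].grid_shape
        for c in cases:
            if c.grid_shape != grid:
                raise ValueError(
                    f"case {c.case_id} grid {c.grid_shape} differs from {grid}")
        return grid

    def _supervised_target(self, case: AnnotatedCase):
        """Released mask for supervision, or None if the case is consistency-only."""
        if case.annotation_status in ("human", "pseudo"):
            return case.gt_mask
        if case.annotation_status == "negative":
            return (case.gt_mask if case.gt_mask is not None
                    else np.zeros(case.grid_shape, dtype=np.int16))
        return None  # withheld_positive without pseudo mask

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a list of :class:`AnnotatedCase` (a supervision-strategy view)."""
        cases = list(X)
        grid = self._validate_cases(cases)
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must be in [0, 1) for training")
        spec = self._spec()
        spec.validate_grid(grid)
        if "translate" in self.allowed_primitives and self.max_translation >= min(grid):
            raise ValueError("max_translation must be smaller than the grid extent")

        ss = np.random.SeedSequence(self.random_state)
        rng_init, rng_order, rng_tf, rng_noise = (
            np.random.default_rng(s) for s in ss.spawn(4))

        net = UNet3D(spec)
        student = net.init_params(rng_init)
        teacher = copy.deepcopy(student)
        state = TeacherStudentState(student=student, teacher=teacher,
                                    ema_decay=self.ema_decay, step=0)
        opt = Adam(student, lr=self.learning_rate)

        n = len(cases)
        bs = max(1, min(self.batch_size, n))
        steps_per_epoch = (n + bs - 1) // bs
        total_steps = self.epochs * steps_per_epoch
        ramp_steps = int(round(self.ramp_fraction * total_steps))

        history = []
        step = 0
        for epoch in range(self.epochs):
            order = rng_order.permutation(n)
            for start in range(0, n, bs):
                batch = [cases[i] for i in order[start:start + bs]]
                lam = losses.sigmoid_ramp(step, ramp_steps, self.lambda_max)
                report = self._train_step(net, state, opt, batch, lam,
                                          rng_tf, rng_noise, step)
                history.append(report)
                step += 1
            if self.verbose:
                log.info("epoch %d/%d  l_seg=%.4f l_con=%.4f lam=%.3f",
                         epoch + 1, self.epochs, history[-1].l_seg,
                         history[-1].l_con, history[-1].lam)

        self.network_ = net
        self.state_ = state
        self.history_ = history
        self.n_steps_ = step
        self.grid_shape_ = grid
        return self

    def _train_step(self, net, state, opt, batch, lam, rng_tf, rng_noise, step):
        grid = batch[0].grid_shape
        xs = np.stack([c.channels for c in batch]).astype(np.float32)
        if self.noise_aug_sd > 0:
            xs = xs + rng_noise.normal(0, self.noise_aug_sd, xs.shape).astype(np.float32)

        # teacher branch: per-case fresh transform of an independently noised copy.
        # With the consistency term disabled outright the branch never enters the
        # gradient, so it is skipped and training reduces to plain supervision.
        use_consistency = self.lambda_max > 0
        if use_consistency:
            transforms = [sample_transform(rng_tf, self.allowed_primitives,
                                           self.max_translation, grid) for _ in batch]
            xt = np.stack([c.channels for c in batch]).astype(np.float32)
            if self.noise_aug_sd > 0:
                xt = xt + rng_noise.normal(0, self.noise_aug_sd,
                                           xt.shape).astype(np.float32)
            xt = np.stack([tf.apply(xt[j]) for j, tf in enumerate(transforms)])

        probs_s, cache = net.forward(state.student, xs, want_cache=True)
        probs_t = net.forward(state.teacher, xt) if use_consistency else None

        nb = len(batch)
        dprobs = np.zeros_like(probs_s)
        sup_idx = [j for j, c in enumerate(batch)
                   if self._supervised_target(c) is not None]
        l_seg = 0.0
        for j in sup_idx:
            mask = self._supervised_target(batch[j])
            status = batch[j].annotation_status
            v, g = losses.segmentation_loss_grad(
                probs_s[j, 1], mask, status, gamma=self.focal_gamma,
                class_weight=self.lesion_class_weight,
                focal_weight=self.focal_weight, dice_weight=self.dice_weight)
            l_seg += v / len(sup_idx)
            dprobs[j, 1] += g / len(sup_idx)

        l_con = 0.0
        if use_consistency:
            for j, tf in enumerate(transforms):
                aligned = tf.apply_inverse(probs_t[j, 1])
                valid = tf.valid_mask(grid)
                v, g = losses.consistency_loss_grad(probs_s[j, 1], aligned, valid)
                l_con += v / nb
                if lam > 0:
                    dprobs[j, 1] += lam * g / nb

        total = l_seg + lam * l_con
        if not np.isfinite(total):
            ids = [c.case_id for c in batch]
            raise RuntimeError(
                f"non-finite loss at step {step} (l_seg={l_seg}, l_con={l_con}) "
                f"on batch {ids}")

        grads = net.backward(state.student, cache, dprobs)
        opt.step(state.student, grads)
        new_state = ema_update(state)
        state.teacher = new_state.teacher
        state.step = new_state.step
        return losses.LossReport(l_seg=float(l_seg), l_con=float(l_con),
                                 lam=float(lam), total=float(total), step=step)

    # -- inference --------------------------------------------------------

    def _infer_params(self) -> dict:
        return (self.state_.teacher if self.use_teacher_for_inference
                else self.state_.student)

    def predict_proba(self, X) -> list:
        """Foreground probability map per case, on the original grid."""
        if not hasattr(self, "state_"):
            raise RuntimeError("estimator is not fitted")
        cases = list(X)
        out = []
        bs = max(1, self.batch_size)
        for start in range(0, len(cases), bs):
            chunk = cases[start:start + bs]
            xs = np.stack([c.channels for c in chunk]).astype(np.float32)
            probs = self.network_.forward(self._infer_params(), xs)
            out.extend(np.clip(probs[j, 1], 0.0, 1.0) for j in range(len(chunk)))
        return out

    def predict(self, X, threshold: float = 0.5) -> list:
        """Binary lesion masks at a fixed probability threshold."""
        return [(p >= threshold).astype(np.int16) for p in self.predict_proba(X)]


def train(view, random_state=None, **params) -> MeanTeacherSegmenter:
    """Functional wrapper: fit a :class:`MeanTeacherSegmenter` on a strategy view."""
    est = MeanTeacherSegmenter(random_state=random_state, **params)
    return est.fit(view)


def generate_pseudo_labels(model: MeanTeacherSegmenter, cases,
                           extraction_params=None) -> tuple:
    """Pseudo-annotate report-positive unannotated cases with a trained model.

    Runs lesion-candidate extraction on each case's probability map and
    binarises the retained candidates into a pseudo mask.  If no candidate
    survives the size filter, the largest connected component above half the
    map maximum is kept as a fallback so that every known-positive case
    receives a nonempty mask where possible; a case whose map is identically
    zero stays unannotated (flagged and logged) and will contribute only the
    consistency term.

    Returns ``(pseudo_cases, skipped_ids)``.
    """
    from .evaluation import ExtractionParams, extract_candidates, fallback_component

    params = extraction_params if extraction_params is not None else ExtractionParams()
    pseudo_cases, skipped = [], []
    probs = model.predict_proba(cases)
    for case, prob in zip(cases, probs):
        if not case.case_positive:
            raise ValueError(
                f"case {case.case_id} is negative; negatives never receive "
                "pseudo-labels (they are supervised as background)")
        candidates = extract_candidates(prob, params, case_id=case.case_id)
        label_map = np.zeros(case.grid_shape, dtype=np.int16)
        for rank, cand in enumerate(candidates, start=1):
            label_map[cand.mask & (label_map == 0)] = rank
        if not candidates:
            fb = fallback_component(prob)
            if fb is not None:
                label_map[fb] = 1
        if label_map.any():
            pseudo_cases.append(replace(case, gt_mask=label_map,
                                        annotation_status="pseudo"))
        else:
            log.warning("pseudo-labeling produced an empty mask for positive "
                        "case %s; excluded from the supervised loss", case.case_id)
            skipped.append(case.case_id)
            pseudo_cases.append(case)
    return pseudo_cases, skipped


def run_strategy(cohort, strategy: str, random_state=None,
                 extraction_params=None, **params):
    """Train one supervision strategy end to end on a generated cohort.

    ``supervised`` and ``fully_supervised`` fit directly on their views.
    ``semi_supervised`` first fits a supervised model, freezes pseudo masks
    for the withheld positives, then fits a fresh model on the enlarged view.
    Returns a dict with the final ``model`` plus, for the semi-supervised
    strategy, the intermediate ``supervised_model`` and skipped case ids.
    """
    from .phantom import split_by_strategy

    if strategy in ("supervised", "fully_supervised"):
        view = split_by_strategy(cohort, strategy)
        return {"model": train(view, random_state=random_state, **params)}

    sup_view = split_by_strategy(cohort, "supervised")
    sup_model = train(sup_view, random_state=random_state, **params)
    withheld = [c for c in cohort.cases if c.annotation_status == "withheld_positive"]
    pseudo_cases, skipped = generate_pseudo_labels(sup_model, withheld,
                                                   extraction_params)
    view = sup_view + pseudo_cases
    model = train(view, random_state=random_state, **params)
    return {"model": model, "supervised_model": sup_model,
            "pseudo_skipped": skipped}


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: MeanTeacherSegmenter, path) -> None:
    """Persist both parameter trees plus the estimator configuration."""
    arrays = {f"student__{k}": v for k, v in model.state_.student.items()}
    arrays.update({f"teacher__{k}": v for k, v in model.state_.teacher.items()})
    arrays["__config"] = np.frombuffer(
        json.dumps({"params": model.get_params(),
                    "ema_decay": model.state_.ema_decay,
                    "step": model.state_.step,
                    "grid_shape": list(model.grid_shape_)}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> MeanTeacherSegmenter:
    data = np.load(path)
    cfg = json.loads(bytes(data["__config"]).decode())
    params = cfg["params"]
    params["allowed_primitives"] = tuple(params["allowed_primitives"])
    model = MeanTeacherSegmenter(**params)
    student = {k[len("student__"):]: data[k] for k in data.files
               if k.startswith("student__")}
    teacher = {k[len("teacher__"):]: data[k] for k in data.files
               if k.startswith("teacher__")}
    model.network_ = UNet3D(model._spec())
    model.state_ = TeacherStudentState(student=student, teacher=teacher,
                                       ema_decay=cfg["ema_decay"], step=cfg["step"])
    model.history_ = []
    model.n_steps_ = cfg["step"]
    model.grid_shape_ = tuple(cfg["grid_shape"])
    return model
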