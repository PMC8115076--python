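"""End-to-end simulated experiments with model-based observers.

Two protocols are provided, mirroring the human designs they stand in for:

* an adaptive **1-up-2-down staircase** over a discrete ladder of stimulus
  levels (proportion-unbalanced ``pi_U`` for texture boundaries, Michelson
  contrast for step boundaries), which equilibrates at the level yielding
  ~70.71% correct;
* a **constant-stimuli masking experiment** presenting a texture target at
  its just-noticeable level together with no masker (``neu``), a congruent
  step boundary in phase (``con_0``) or in opposite phase (``con_180``), or
  an orthogonally oriented step boundary (``inc``).

Observers are Bernoulli responders driven by one of the decision models:
an SDT observer responds correctly with the probability its psychometric
function assigns to the trial's stimulus level (it has no image pathway and
therefore ignores maskers); IC-1 and IC-2 observers look at the rendered
stimulus.  Every run is bit-identical given its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ltbseg import features as feat
from ltbseg import models
from ltbseg.stimulus import (
    LTBSpec, LSBSpec, CompositeSpec, StimulusImage,
    LEFT_OBLIQUE, RIGHT_OBLIQUE, compose, snap_pi_u,
)

ORIENT = {"L": LEFT_OBLIQUE, "R": RIGHT_OBLIQUE}


@dataclass
class TrialRecord:
    """One simulated trial."""

    condition: str  #: one of neu / con_0 / con_180 / inc / plain
    level: float  #: stimulus level (pi_U or c_M)
    true_orientation: str  #: "L" or "R"
    response: str  #: "L" or "R"
    correct: bool
    stimulus_ref: object = None  #: generating spec, when a stimulus was built
    seed: Optional[int] = None


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "condition": t.condition, "level": t.level,
        "true_orientation": t.true_orientation, "response": t.response,
        "correct": t.correct, "seed": t.seed} for t in trials])


@dataclass
class SimulatedObserver:
    """A stochastic observer wrapping one of the decision models.

    ``model_id`` is ``"sdt"``, ``"ic1"`` or ``"ic2"`` with the matching
    parameter record.  Image-computable observers evaluate their model on the
    rendered stimulus; the SDT observer only sees the stimulus level.
    """

    model_id: str
    params: object
    sigma_c: float = 4.0
    support_halfwidth: int = 16
    order: str = "rectify_then_pool"

    def prob_correct_at_level(self, level: float) -> float:
        if self.model_id != "sdt":
            raise TypeError("only the SDT observer responds to bare levels")
        return models.sdt_pc(level, self.params)

    def prob_R(self, image: StimulusImage) -> float:
        """Probability of a right-oblique response to a rendered stimulus."""
        if self.model_id == "ic1":
            return models.ic1_prob_R(feat.measure(image), self.params)
        if self.model_id == "ic2":
            return models.ic2_prob_R(image, self.params, self.sigma_c,
                                     self.support_halfwidth, self.order)
        raise TypeError(f"observer model {self.model_id!r} has no image pathway")

    def respond(self, true_orientation: str, rng: np.random.Generator,
                image: Optional[StimulusImage] = None,
                level: Optional[float] = None) -> tuple[str, bool]:
        """Draw a Bernoulli response; returns ``(response, correct)``."""
        if self.model_id == "sdt":
            correct = rng.random() < self.prob_correct_at_level(level)
            resp = true_orientation if correct else (
                "L" if true_orientation == "R" else "R")
        else:
            p_r = self.prob_R(image)
            resp = "R" if rng.random() < p_r else "L"
            correct = resp == true_orientation
        return resp, correct


@dataclass
class StaircaseState:
    """Bookkeeping for a 1-up-2-down staircase run."""

    ladder: np.ndarray
    index: int
    consecutive_correct: int = 0
    reversals: list = field(default_factory=list)  #: (trial, level) pairs
    trials_done: int = 0
    _last_direction: int = 0

    def step(self, correct: bool) -> None:
        """Apply the 1-up-2-down rule after one trial.

        Any error moves one ladder step up (easier); two consecutive correct
        responses move one step down (harder).  The index clips at the ladder
        ends; a reversal is logged whenever the movement direction flips.
        """
        level_now = float(self.ladder[self.index])
        self.trials_done += 1
        move = 0
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= 2:
                self.consecutive_correct = 0
                move = -1
        else:
            self.consecutive_correct = 0
            move = +1
        if move:
            if self._last_direction and move != self._last_direction:
                self.reversals.append((self.trials_done, level_now))
            self._last_direction = move
            self.index = int(np.clip(self.index + move, 0, len(self.ladder) - 1))


def reversal_mean(state: StaircaseState, skip: int = 4,
                  even: bool = True) -> float:
    """Mean reversal level after discarding the first ``skip`` reversals.

    With ``even=True`` the count is truncated to an even number so that up-
    and down-going reversals are averaged in pairs, removing the sawtooth
    bias.
    """
    levels = [lvl for _, lvl in state.reversals[skip:]]
    if even and len(levels) % 2:
        levels = levels[:-1]
    if not levels:
        raise ValueError("no reversals left after burn-in")
    return float(np.mean(levels))


def run_staircase(observer: SimulatedObserver, ladder, n_trials: int = 250,
                  start: str = "highest", seed: int = 0,
                  stimulus_factory: Optional[Callable] = None,
                  ) -> tuple[list[TrialRecord], StaircaseState]:
    """Simulate a 1-up-2-down staircase over a sorted ladder of levels.

    Each trial randomizes the true orientation (L/R) and the phase (which
    half of the disc is brighter).  For image-computable observers a
    ``stimulus_factory(level, orientation, phase, seed)`` must render the
    stimulus; the SDT observer responds from its psychometric function
    directly.  Returns the trial records and the final staircase state.
    """
    ladder = np.asarray(ladder, dtype=float)
    if ladder.size == 0:
        raise ValueError("ladder must be non-empty")
    if np.any(np.diff(ladder) <= 0):
        raise ValueError("ladder must be sorted ascending")
    rng = np.random.default_rng(seed)
    state = StaircaseState(ladder=ladder,
                           index=len(ladder) - 1 if start == "highest" else 0)
    trials = []
    for _ in range(n_trials):
        level = float(ladder[state.index])
        true = "R" if rng.random() < 0.5 else "L"
        phase = 0 if rng.random() < 0.5 else 180
        if observer.model_id == "sdt":
            resp, correct = observer.respond(true, rng, level=level)
            ref, tseed = None, None
        else:
            if stimulus_factory is None:
                raise ValueError("image-computable observers need a "
                                 "stimulus_factory")
            tseed = int(rng.integers(2**31))
            image = stimulus_factory(level, ORIENT[true], phase, tseed)
            resp, correct = observer.respond(true, rng, image=image)
            ref = image.spec
        trials.append(TrialRecord("plain", level, true, resp, correct, ref, tseed))
        state.step(correct)
    return trials, state


def _balanced_orientations(n: int, rng: np.random.Generator) -> list[str]:
    half = n // 2
    orients = ["L"] * half + ["R"] * (n - half)
    rng.shuffle(orients)
    return orients


def run_masking_experiment(observer: SimulatedObserver, jnd_ltb: float,
                           jnd_lsb: float, n_per_condition: int = 200,
                           ltb_template: Optional[LTBSpec] = None,
                           lsb_template: Optional[LSBSpec] = None,
                           seed: int = 0, keep_images: bool = False,
                           max_snap_shift: float = 0.125):
    """Constant-stimuli masking experiment.

    Presents the texture target at ``pi_U = jnd_ltb`` under four conditions
    with trial counts ``n / n/2 / n/2 / n`` for ``neu / con_0 / con_180 /
    inc``, the masking step boundary at ``c_M = jnd_lsb``.  Orientations are
    balanced within each condition to within one trial; target phase is
    random each trial.  Raises if snapping ``jnd_ltb`` to a feasible
    micropattern count moves it by more than ``max_snap_shift`` (one ladder
    step of the standard design).

    Returns trial records, and the rendered stimuli too when
    ``keep_images=True``.
    """
    ltb_template = ltb_template if ltb_template is not None else LTBSpec()
    lsb_template = lsb_template if lsb_template is not None else LSBSpec(
        image_size=ltb_template.image_size,
        disc_radius=ltb_template.disc_radius,
        taper_width=ltb_template.taper_width)
    snapped = snap_pi_u(jnd_ltb, ltb_template.n_p)
    if abs(snapped - jnd_ltb) > max_snap_shift:
        raise ValueError(
            f"pi_U={jnd_ltb} snaps to {snapped} for n_p={ltb_template.n_p}, "
            f"moving by more than {max_snap_shift}")

    rng = np.random.default_rng(seed)
    plan = [("neu", n_per_condition), ("con_0", n_per_condition // 2),
            ("con_180", n_per_condition // 2), ("inc", n_per_condition)]
    trials, images = [], []
    import dataclasses as dc
    for condition, n_cond in plan:
        for true in _balanced_orientations(n_cond, rng):
            phase = 0 if rng.random() < 0.5 else 180
            tseed = int(rng.integers(2**31))
            ltb = dc.replace(ltb_template, pi_U=snapped, orientation=ORIENT[true],
                             phase=phase, seed=tseed)
            if condition == "neu":
                spec = CompositeSpec(ltb, None, "neu")
            elif condition == "inc":
                other = "L" if true == "R" else "R"
                lsb_phase = 0 if rng.random() < 0.5 else 180
                spec = CompositeSpec(ltb, dc.replace(
                    lsb_template, c_M=jnd_lsb, orientation=ORIENT[other],
                    phase=lsb_phase), "inc")
            else:
                lsb_phase = phase if condition == "con_0" else (180 - phase)
                spec = CompositeSpec(ltb, dc.replace(
                    lsb_template, c_M=jnd_lsb, orientation=ORIENT[true],
                    phase=lsb_phase), condition)
            image = compose(spec)
            if observer.model_id == "sdt":
                resp, correct = observer.respond(true, rng, level=snapped)
            else:
                resp, correct = observer.respond(true, rng, image=image)
            trials.append(TrialRecord(condition, snapped, true, resp, correct,
                                      spec, tseed))
            if keep_images:
                images.append(image)
    if keep_images:
        return trials, images
    return trials


def measure_lsb_jnd(observer: SimulatedObserver, ladder=None,
                    n_trials: int = 250, with_uninformative_ltb: bool = False,
                    ltb_template: Optional[LTBSpec] = None,
                    lsb_template: Optional[LSBSpec] = None, seed: int = 0,
                    target: float = 0.75) -> float:
    """Step-boundary threshold from a staircase plus psychometric refit.

    Runs a 1-up-2-down staircase over the Michelson-contrast ladder, fits
    the SDT psychometric function to all trials, and returns the ``target``
    (default 75%-correct) contrast.  With ``with_uninformative_ltb`` the
    step boundary is superimposed on a cue-free texture (pi_U = 0) of random
    orientation, the control used to measure masker visibility in context.
    """
    import dataclasses as dc

    from ltbseg import fitting
    from ltbseg.stimulus import lsb_contrast_ladder

    if ladder is None:
        ladder = lsb_contrast_ladder()
    lsb_template = lsb_template if lsb_template is not None else LSBSpec()
    ltb_template = ltb_template if ltb_template is not None else LTBSpec(
        image_size=lsb_template.image_size,
        disc_radius=lsb_template.disc_radius,
        taper_width=lsb_template.taper_width)
    pad_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    def factory(level, orientation, phase, s):
        lsb = dc.replace(lsb_template, c_M=level, orientation=orientation,
                         phase=phase)
        if not with_uninformative_ltb:
            from ltbseg.stimulus import make_lsb
            return make_lsb(lsb)
        pad_orient = (LEFT_OBLIQUE if pad_rng.random() < 0.5
                      else RIGHT_OBLIQUE)
        ltb = dc.replace(ltb_template, pi_U=0.0, orientation=pad_orient,
                         phase=0 if pad_rng.random() < 0.5 else 180, seed=s)
        relation = "inc" if pad_orient != orientation else (
            "con_0" if ltb.phase == phase else "con_180")
        return compose(CompositeSpec(ltb, lsb, relation))

    trials, _ = run_staircase(observer, ladder, n_trials=n_trials, seed=seed,
                              stimulus_factory=factory)
    df = trials_to_frame(trials)
    grouped = df.groupby("level")["correct"].agg(["sum", "count"])
    fit = fitting.fit_sdt(grouped.index.to_numpy(),
                          grouped["sum"].to_numpy(),
                          grouped["count"].to_numpy())
    return fitting.threshold(fit.params, target=target)


def accuracy_by_condition(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Correct/total counts and proportion correct per condition."""
    df = trials_to_frame(trials)
    out = df.groupby("condition")["correct"].agg(["sum", "count"])
    out.columns = ["n_correct", "n_trials"]
    out["proportion"] = out["n_correct"] / out["n_trials"]
    return out
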