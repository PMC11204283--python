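"""End-to-end demo pipeline: simulate -> calibrate -> fuse -> detect ->
optimize segmentation -> synthesize -> train -> evaluate.

Each stage records its inputs, outputs and metrics into a JSON manifest so
any stage can be re-run standalone from prior artifacts.  The bundled demo
configuration is deliberately small (a few words and sentences, a thin
network) so a full run completes in minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np

from . import decoder as dec
from .config import RunConfig
from .detection import activity_indicator, detect_segments, smooth_indicator
from .io import save_json, write_speech_bank
from .scenarios import (
    actual_sentence_samples,
    make_sentence_book,
    make_vocabulary,
    run_interference_test,
    run_turntable_protocol,
)
from .motion_sim import sample_word
from .segparam import BoConfig, optimize_segmentation
from .synthesis import SegmentationParams, SynthesisConfig, build_training_corpus

__all__ = ["run_pipeline"]


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full stage chain and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def stage(name: str):
        manifest["stages"][name] = {"t_start": time.time()}
        return manifest["stages"][name]

    try:
        # -- motion acquisition: calibration + interference sanity ----------
        s = stage("calibration")
        cal = run_turntable_protocol(seed=int(rng.integers(2**31)), dwell_s=1.0)
        s.update(max_error_deg=cal["max_error_deg"], per_axis=cal["per_axis"])

        s = stage("interference")
        interf = run_interference_test(seed=int(rng.integers(2**31)), segment_s=6.0)
        s.update(**{k: v for k, v in interf.items() if k.startswith("max")})

        # -- word bank -------------------------------------------------------
        s = stage("word_bank")
        vocab = make_vocabulary(config.n_words, seed=config.seed)
        bank = {
            wid: sample_word(tpl, n=20, length_sd=0.1, amp_sd=0.1, seed=config.seed)
            for wid, tpl in vocab.items()
        }
        bank_path = out / "word_bank.h5"
        write_speech_bank(bank_path, [s_ for reps in bank.values() for s_ in reps])
        s.update(n_words=len(bank), path=str(bank_path))

        # -- speech detection sanity on a synthetic indicator ----------------
        s = stage("detection")
        fs = 100.0
        omega = np.zeros((int(6 * fs), 3))
        omega[200:350, 1] = 20.0
        segs = detect_segments(smooth_indicator(activity_indicator(omega)))
        s.update(n_segments=len(segs))

        # -- sentence book, ground truth, parameter optimization -------------
        s = stage("optimize_params")
        book = make_sentence_book(list(vocab), config.n_sentences,
                                  config.words_per_sentence, seed=config.seed)
        true_params = {
            sid: SegmentationParams(
                ratios=[(float(r), float(e)) for r, e in
                        rng.uniform(0.1, 0.3, size=(len(words), 2))]
            )
            for sid, words in book.items()
        }
        sid0 = next(iter(book))
        actual = actual_sentence_samples(
            book[sid0], vocab, true_params[sid0], n_samples=2,
            jitter_sd=0.0, word_sd=0.05, seed=config.seed,
        )
        sets = [bank[w][:2] for w in book[sid0]]
        bo_cfg = BoConfig(budget=min(config.bo.budget, 24), seed=config.seed)
        est, trace = optimize_segmentation(sets, actual, bo_cfg)
        s.update(
            sentence=sid0,
            estimated=est.vector.tolist(),
            true=true_params[sid0].vector.tolist(),
            best_objective=float(trace["y"][trace["best_index"]]),
        )

        # -- corpus synthesis -------------------------------------------------
        s = stage("synthesize")
        syn_cfg = SynthesisConfig(pairs_per_sample=10, seed=config.seed)
        corpus, corpus_manifest = build_training_corpus(book, bank, true_params, syn_cfg)
        s.update(total=corpus_manifest["total"],
                 per_sentence={k: v["total"] for k, v in corpus_manifest["sentences"].items()})

        # -- decoder ----------------------------------------------------------
        s = stage("train_sentences")
        test = [
            smp.copy(label=sid)
            for sid, words in book.items()
            for smp in actual_sentence_samples(words, vocab, true_params[sid],
                                               n_samples=3, jitter_sd=0.05,
                                               word_sd=0.1, seed=config.seed + 1)
        ]
        ds = dec.prepare_train_test(corpus, test)
        dcfg = dec.DecoderConfig(n_blocks=config.decoder.n_blocks,
                                 filters=min(config.decoder.filters, 16),
                                 epochs=min(config.decoder.epochs, 8),
                                 batch_size=config.decoder.batch_size,
                                 seed=config.seed)
        model = dec.build(dcfg, len(ds.classes), ds.max_length)
        history = dec.train(model, ds, dcfg, checkpoint=str(out / "decoder.npz"))
        s.update(final_loss=history["loss"][-1], epochs=dcfg.epochs)

        s = stage("evaluate")
        metrics = dec.evaluate(model, ds)
        s.update(accuracy=metrics["accuracy"],
                 confusion_hash=_hash_array(metrics["confusion"]))
    except Exception as exc:
        manifest["failed_stage"] = list(manifest["stages"])[-1]
        manifest["error"] = repr(exc)
        save_json(out / "manifest.json", manifest)
        raise

    for st in manifest["stages"].values():
        st["elapsed_s"] = round(time.time() - st.pop("t_start"), 2)
    save_json(out / "manifest.json", manifest)
    return manifest
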