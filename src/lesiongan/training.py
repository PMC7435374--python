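"""Alternating optimization of the generator and the two discriminators.

One training run targets one modality.  Each step draws a donor pair
(A, B), composites A's tumor onto B's brain background to get the virtual
label s_ab, and:

1. updates the global discriminator on (x_b, s_b) as real versus
   (G(s_ab, x_a), s_ab) as fake;
2. updates the local discriminator on independently located 64x64 crops
   of x_b (real) versus the generated image (fake);
3. updates the generator on the weighted sum of the regional perceptual
   loss, the regional L1 loss and the two generator-side least-squares
   adversarial terms.

Everything is seeded through one ``numpy`` generator whose state is
checkpointed, so runs are bit-reproducible on CPU and resumable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .compositor import InadmissiblePairError, composite_label
from .losses import (
    LossRecord, LossWeights, lsgan_d_loss, lsgan_g_loss,
    regional_l1_loss, regional_perceptual_loss, total_loss,
)
from .networks import (
    FeatureExtractor, build_generator, build_global_discriminator,
    build_local_discriminator,
)
from .nn import Adam, Tensor, concat
from .phantom import PhantomCase, generate_phantom_case, read_case_nifti
from .preprocessing import (
    N_CLASSES, SemanticLabel, brain_mask_from_image, encode_label,
    extract_slices, normalize_intensity, one_hot, resize_slice,
)

GEN_IN_CHANNELS = N_CLASSES + 1  # one-hot label stack + conditioning image
DISC_IN_CHANNELS = N_CLASSES + 1


@dataclasses.dataclass
class TrainConfig:
    iterations: int = 200
    batch_size: int = 1
    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    crop_size: int = 64
    image_size: int = 256
    base_width_scale: float = 1.0
    seed: int = 0
    modality: str = "flair"
    max_dropped: float = 0.05
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    perceptual_tags: tuple[str, str] = ("conv3_4", "conv4_4")
    extractor_blocks: int = 4
    data_dir: str | None = None       # BraTS-layout NIfTI directory; None -> phantoms
    n_phantom_cases: int = 4
    phantom_shape: tuple[int, int, int] = (16, 64, 64)
    slice_low: int = 0
    slice_high: int | None = None
    out_dir: str = "runs/lesiongan"
    checkpoint_every: int = 100
    log_every: int = 1
    resume_from: str | None = None

    def __post_init__(self) -> None:
        if self.crop_size > self.image_size:
            raise ValueError("crop_size must not exceed image_size")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "weights" in raw and isinstance(raw["weights"], dict):
            raw["weights"] = LossWeights(**raw["weights"])
        for key in ("betas", "perceptual_tags", "phantom_shape"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# Dataset of preprocessed slices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SliceSample:
    image: np.ndarray          # normalized [0,1], (H, W)
    label: SemanticLabel


class SliceDataset:
    """Per-patient pools of preprocessed (image, label) slices of one modality."""

    def __init__(self, cases: list[PhantomCase], modality: str, image_size: int,
                 slice_low: int = 0, slice_high: int | None = None):
        self.modality = modality
        self.image_size = image_size
        self.tumor_slices: dict[str, list[SliceSample]] = {}
        self.brain_slices: dict[str, list[SliceSample]] = {}
        for case in cases:
            if modality not in case.volumes:
                raise ValueError(f"case {case.case_id} lacks modality {modality!r}")
            high = slice_high if slice_high is not None else case.shape[0]
            raw_slices = extract_slices(case.volumes[modality], slice_low, high)
            raw_labels = extract_slices(case.label_volume, slice_low, high)
            tumor_pool: list[SliceSample] = []
            brain_pool: list[SliceSample] = []
            for offset, (img, lab) in enumerate(zip(raw_slices, raw_labels)):
                idx = slice_low + offset
                if not (img > 0).any():
                    continue
                mask = brain_mask_from_image(img)
                if ((lab > 0) & ~mask).any():
                    continue  # tumor clipped by slice geometry; unusable slice
                sem = encode_label(lab, mask, patient_id=case.case_id, slice_index=idx)
                cls = resize_slice(sem.classes, image_size, is_label=True)
                sem = SemanticLabel(classes=cls, patient_id=case.case_id, slice_index=idx)
                pix = resize_slice(img.astype(np.float64), image_size, is_label=False)
                if pix.max() == pix.min():
                    continue
                sample = SliceSample(image=normalize_intensity(pix), label=sem)
                brain_pool.append(sample)
                if sem.has_tumor():
                    tumor_pool.append(sample)
            if brain_pool:
                self.brain_slices[case.case_id] = brain_pool
            if tumor_pool:
                self.tumor_slices[case.case_id] = tumor_pool

    @property
    def patient_ids(self) -> list[str]:
        # donors must carry tumor; backgrounds only need brain slices
        return sorted(self.tumor_slices)

    def __len__(self) -> int:
        return sum(len(v) for v in self.brain_slices.values())


@dataclasses.dataclass
class Batch:
    x_a: np.ndarray            # (B, 1, H, W)
    s_ab: np.ndarray           # (B, n_classes, H, W) one-hot composite labels
    x_b: np.ndarray
    s_b: np.ndarray
    tumor_masks: np.ndarray    # (B, H, W) bool
    tissue_masks: np.ndarray
    provenance: list[tuple[tuple[str, int], tuple[str, int]]]


def random_crop(image, size: int, rng: np.random.Generator):
    """Uniform random square crop; returns (crop, (top, left)).

    Accepts a numpy array (H, W) / (N, C, H, W) or an autograd tensor, in
    which case gradients flow back into the uncropped image.
    """
    is_tensor = isinstance(image, Tensor)
    h, w = (image.shape[-2], image.shape[-1])
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image dims ({h}, {w})")
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    if is_tensor:
        x = image if image.ndim == 4 else image.reshape(1, 1, h, w)
        return x.crop2d(top, left, size, size), (top, left)
    return np.asarray(image)[..., top:top + size, left:left + size], (top, left)


def make_batch(dataset: SliceDataset, pairs: list[tuple[str, str]] | None,
               rng: np.random.Generator, batch_size: int = 1,
               max_dropped: float = 0.05, max_retries: int = 50) -> Batch:
    """Sample donor pairs and composite their labels into a training batch."""
    donor_ids = dataset.patient_ids
    if len(dataset.brain_slices) < 2 or not donor_ids:
        raise ValueError("need at least 2 patients with slices (and one tumor donor)")
    if pairs is None:
        pairs = [(a, b) for a in donor_ids for b in sorted(dataset.brain_slices) if a != b]
    if not pairs:
        raise ValueError("no donor pairs available")

    xs_a, labels_ab, xs_b, labels_b = [], [], [], []
    tumor_masks, tissue_masks, provenance = [], [], []
    for _ in range(batch_size):
        composite = None
        for _attempt in range(max_retries):
            a, b = pairs[int(rng.integers(len(pairs)))]
            sample_a = dataset.tumor_slices[a][int(rng.integers(len(dataset.tumor_slices[a])))]
            pool_b = dataset.brain_slices[b]
            sample_b = pool_b[int(rng.integers(len(pool_b)))]
            try:
                composite = composite_label(sample_a.label, sample_b.label, max_dropped)
            except InadmissiblePairError:
                continue
            break
        if composite is None:
            raise RuntimeError(f"no admissible donor pair found in {max_retries} draws")
        from .preprocessing import region_masks
        masks = region_masks(sample_a.label, sample_b.label)
        xs_a.append(sample_a.image[None])
        labels_ab.append(one_hot(composite.label))
        xs_b.append(sample_b.image[None])
        labels_b.append(one_hot(sample_b.label))
        tumor_masks.append(masks.tumor_mask)
        tissue_masks.append(masks.tissue_mask)
        provenance.append((composite.tumor_donor, composite.background_donor))

    return Batch(
        x_a=np.stack(xs_a), s_ab=np.stack(labels_ab),
        x_b=np.stack(xs_b), s_b=np.stack(labels_b),
        tumor_masks=np.stack(tumor_masks), tissue_masks=np.stack(tissue_masks),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Networks + optimizers bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GanNetworks:
    generator: object
    d_global: object
    d_local: object
    extractor: FeatureExtractor


@dataclasses.dataclass
class GanOptimizers:
    g: Adam
    d_g: Adam
    d_l: Adam


def build_networks(config: TrainConfig) -> GanNetworks:
    scale = config.base_width_scale
    return GanNetworks(
        generator=build_generator(GEN_IN_CHANNELS, base_width_scale=scale,
                                  seed=config.seed),
        d_global=build_global_discriminator(DISC_IN_CHANNELS, base_width_scale=scale,
                                            seed=config.seed + 1),
        d_local=build_local_discriminator(base_width_scale=scale, seed=config.seed + 2,
                                          crop_size=config.crop_size, strict=False),
        extractor=FeatureExtractor(width_scale=scale, seed=config.seed + 3,
                                   n_blocks=config.extractor_blocks),
    )


def build_optimizers(nets: GanNetworks, config: TrainConfig) -> GanOptimizers:
    lr, betas = config.learning_rate, tuple(config.betas)
    return GanOptimizers(
        g=Adam(nets.generator.parameters(), lr=lr, betas=betas),
        d_g=Adam(nets.d_global.parameters(), lr=lr, betas=betas),
        d_l=Adam(nets.d_local.parameters(), lr=lr, betas=betas),
    )


def train_step(batch: Batch, nets: GanNetworks, w: LossWeights,
               optim: GanOptimizers, rng: np.random.Generator,
               crop_size: int = 64, step: int = 0,
               perceptual_tags: tuple[str, str] = ("conv3_4", "conv4_4")) -> LossRecord:
    """One D-then-G alternation; returns the step's loss record."""
    x_a = Tensor(batch.x_a)
    s_ab = Tensor(batch.s_ab)
    x_b = Tensor(batch.x_b)
    s_b = Tensor(batch.s_b)

    y = nets.generator(concat([s_ab, x_a], axis=1))
    y_detached = y.detach()

    # -- global discriminator -------------------------------------------
    # The update halves the objective (CycleGAN convention: D learns at half
    # rate relative to G); the recorded loss is the unhalved value.
    optim.d_g.zero_grad()
    d_real = nets.d_global(concat([x_b, s_b], axis=1))
    d_fake = nets.d_global(concat([y_detached, s_ab], axis=1))
    loss_dg = lsgan_d_loss(d_real, d_fake)
    (0.5 * loss_dg).backward()
    optim.d_g.step()

    # -- local discriminator ---------------------------------------------
    optim.d_l.zero_grad()
    crop_real, _ = random_crop(x_b, crop_size, rng)
    crop_fake, _ = random_crop(y_detached, crop_size, rng)
    loss_dl = lsgan_d_loss(nets.d_local(crop_real), nets.d_local(crop_fake))
    (0.5 * loss_dl).backward()
    optim.d_l.step()

    # -- generator ---------------------------------------------------------
    optim.g.zero_grad()
    from .preprocessing import RegionMasks  # local import to avoid cycle at module load
    masks = RegionMasks(tumor_mask=batch.tumor_masks, tissue_mask=batch.tissue_masks)
    l_rp = regional_perceptual_loss(y, x_b, x_a, masks, nets.extractor, w,
                                    tags=perceptual_tags)
    l_1 = regional_l1_loss(y, x_b, batch.tissue_masks)
    adv_global = lsgan_g_loss(nets.d_global(concat([y, s_ab], axis=1)))
    crop_y, _ = random_crop(y, crop_size, rng)
    adv_local = lsgan_g_loss(nets.d_local(crop_y))
    g_objective = total_loss(l_rp, l_1, adv_global + adv_local, w)
    g_objective.backward()
    optim.g.step()

    l_g = float(loss_dg)
    l_l = float(loss_dl)
    l_adv = l_g + l_l
    record = LossRecord(
        step=step, l_rp=float(l_rp), l_1=float(l_1), l_g=l_g, l_l=l_l,
        l_adv=l_adv,
        total=w.lam * float(l_rp) + w.mu * float(l_1) + w.gamma * l_adv,
    )
    return record


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, nets: GanNetworks, optim: GanOptimizers,
                    step: int, rng: np.random.Generator, config: TrainConfig) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for name, net in (("g", nets.generator), ("dg", nets.d_global),
                      ("dl", nets.d_local), ("vgg", nets.extractor)):
        for k, v in net.state_dict().items():
            arrays[f"{name}/{k}"] = v
    for name, opt in (("g", optim.g), ("dg", optim.d_g), ("dl", optim.d_l)):
        arrays[f"opt_{name}/t"] = np.array(opt.t)
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            arrays[f"opt_{name}/m{i}"] = m
            arrays[f"opt_{name}/v{i}"] = v
    meta = {
        "step": step,
        "rng_state": rng.bit_generator.state,
        "config": config.to_dict(),
        "format_version": 1,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path, nets: GanNetworks, optim: GanOptimizers | None = None):
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version in {path}")
        for name, net in (("g", nets.generator), ("dg", nets.d_global),
                          ("dl", nets.d_local), ("vgg", nets.extractor)):
            state = {k[len(name) + 1:]: data[k] for k in data.files
                     if k.startswith(f"{name}/")}
            net.load_state_dict(state)
        if optim is not None:
            for name, opt in (("g", optim.g), ("dg", optim.d_g), ("dl", optim.d_l)):
                opt.t = int(data[f"opt_{name}/t"])
                opt.m = [np.array(data[f"opt_{name}/m{i}"]) for i in range(len(opt.m))]
                opt.v = [np.array(data[f"opt_{name}/v{i}"]) for i in range(len(opt.v))]
    return meta


@dataclasses.dataclass
class TrainResult:
    checkpoint_path: Path
    log_path: Path
    records: list[LossRecord]


def load_dataset(config: TrainConfig) -> SliceDataset:
    """Dataset from a BraTS-layout directory, or seeded phantoms when none given."""
    if config.data_dir is not None:
        directory = Path(config.data_dir)
        case_ids = sorted({f.name[:-len("_seg.nii.gz")]
                           for f in directory.glob("*_seg.nii.gz")})
        if not case_ids:
            raise FileNotFoundError(f"no *_seg.nii.gz cases under {directory}")
        cases = [read_case_nifti(directory, cid) for cid in case_ids]
    else:
        cases = [generate_phantom_case(config.seed * 1000 + i, config.phantom_shape,
                                       [config.modality])
                 for i in range(config.n_phantom_cases)]
    return SliceDataset(cases, config.modality, config.image_size,
                        config.slice_low, config.slice_high)


def train(config: TrainConfig, dataset: SliceDataset | None = None) -> TrainResult:
    """Run the full loop; writes a JSONL loss log and periodic checkpoints."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "losses.jsonl"
    ckpt_path = out_dir / "checkpoint.npz"

    dataset = dataset or load_dataset(config)
    nets = build_networks(config)
    optim = build_optimizers(nets, config)
    rng = np.random.default_rng(config.seed)
    start_step = 0
    if config.resume_from:
        meta = load_checkpoint(config.resume_from, nets, optim)
        start_step = int(meta["step"])
        rng.bit_generator.state = meta["rng_state"]

    records: list[LossRecord] = []
    mode = "a" if config.resume_from else "w"
    with open(log_path, mode) as log:
        for step in range(start_step, config.iterations):
            batch = make_batch(dataset, None, rng, config.batch_size, config.max_dropped)
            try:
                record = train_step(batch, nets, config.weights, optim, rng,
                                    crop_size=config.crop_size, step=step,
                                    perceptual_tags=config.perceptual_tags)
            except ValueError as exc:
                raise RuntimeError(f"aborting at step {step}: {exc}") from exc
            records.append(record)
            if step % config.log_every == 0:
                log.write(json.dumps(record.to_dict()) + "\n")
            if config.checkpoint_every and (step + 1) % config.checkpoint_every == 0:
                save_checkpoint(ckpt_path, nets, optim, step + 1, rng, config)
    save_checkpoint(ckpt_path, nets, optim, config.iterations, rng, config)
    return TrainResult(checkpoint_path=ckpt_path, log_path=log_path, records=records)
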