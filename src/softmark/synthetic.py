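"""Synthetic face cohort generator with exact ground-truth landmarks.

Generates schematic frontal/profile face images whose statistical
structure matches the study cohort this package evaluates against:
~98 subjects, one frontal and one profile image each, original image
dimensions drawn from Normal(1034, 56) x Normal(1150, 57) pixels
(truncated at +/-3 SD), a fixed 0.1 mm/pixel export scale, and the
22/15-landmark schemas.  Faces are 2D parametric templates (ellipse head
plus drawn feature curves), not photorealistic renders: what matters
downstream is that every landmark sits on visible intensity structure so
a coordinate-regression network can learn to localize it, and that the
landmark geometry varies across subjects through a small latent shape
vector.

A simulated manual annotator (isotropic Gaussian jitter in millimetres)
models the intra-observer re-annotation process; its default jitter is
calibrated once so that two simulated annotation rounds give a mean
intraclass correlation inside the study's reported 0.85-0.95 band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .schemas import (
    AnnotatedImage,
    FRONTAL_VIEW,
    PROFILE_VIEW,
    PointAnnotation,
    get_schema,
    points_from_array,
)

# Cohort-level distribution targets (original export resolution).
MEAN_WIDTH_PX = 1034.0
SD_WIDTH_PX = 56.0
MEAN_HEIGHT_PX = 1150.0
SD_HEIGHT_PX = 57.0
DIM_TRUNC_SD = 3.0  # dimension draws truncated at +/-3 SD

BASE_SCALE_MM_PER_PX = 0.1

#: Latent shape axes, each a ~N(0,1) perturbation truncated at +/-2.5 SD.
LATENT_NAMES = ("eye_spacing", "nose_length", "mouth_width",
                "jaw_angle", "hairline_height", "asymmetry")
LATENT_TRUNC_SD = 2.5

#: Default annotator jitter (mm per axis), calibrated by simulation so two
#: annotation rounds on 20 images give mean ICC(2,1) in [0.85, 0.95].
DEFAULT_JITTER_SD_MM = 0.9


@dataclass(frozen=True)
class SubjectParams:
    """Latent description of one synthetic subject."""

    subject_id: str
    face_width_px: float
    face_height_px: float
    shape_latents: tuple[float, ...]
    skin_tone: float
    rng_seed: int

    def latent(self, name: str) -> float:
        return self.shape_latents[LATENT_NAMES.index(name)]


@dataclass(frozen=True)
class AnnotatorModel:
    """Simulated manual annotator: isotropic Gaussian jitter in mm."""

    jitter_sd_mm: float = DEFAULT_JITTER_SD_MM
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.jitter_sd_mm > 0:
            raise ValueError("jitter_sd_mm must be positive")


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                      nsd: float, size=None) -> np.ndarray | float:
    """Rejection-sampled Normal(loc, scale) truncated at +/- nsd SDs."""
    out = rng.normal(loc, scale, size=size)
    arr = np.atleast_1d(np.asarray(out, dtype=float))
    bad = np.abs(arr - loc) > nsd * scale
    while bad.any():
        arr[bad] = rng.normal(loc, scale, size=int(bad.sum()))
        bad = np.abs(arr - loc) > nsd * scale
    return float(arr[0]) if size is None else arr


def sample_subject(index: int, master_seed: int) -> SubjectParams:
    """Draw one subject's parameters, deterministic in (index, master_seed)."""
    if index < 0:
        raise ValueError("index must be >= 0")
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    rng = np.random.default_rng(ss)
    width = _truncated_normal(rng, MEAN_WIDTH_PX, SD_WIDTH_PX, DIM_TRUNC_SD)
    height = _truncated_normal(rng, MEAN_HEIGHT_PX, SD_HEIGHT_PX, DIM_TRUNC_SD)
    latents = _truncated_normal(rng, 0.0, 1.0, LATENT_TRUNC_SD,
                                size=len(LATENT_NAMES))
    skin_tone = float(rng.uniform(0.25, 0.85))
    render_seed = int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    return SubjectParams(
        subject_id=f"subj{index:03d}",
        face_width_px=width,
        face_height_px=height,
        shape_latents=tuple(float(v) for v in latents),
        skin_tone=skin_tone,
        rng_seed=render_seed,
    )


# ---------------------------------------------------------------------------
# Landmark templates
# ---------------------------------------------------------------------------

def _frontal_fractions(p: SubjectParams) -> dict[str, tuple[float, float]]:
    """Frontal landmark positions as (x, y) fractions of (width, height)."""
    eye = p.latent("eye_spacing")
    nose = p.latent("nose_length")
    mouth = p.latent("mouth_width")
    jaw = p.latent("jaw_angle")
    hair = p.latent("hairline_height")
    asym = p.latent("asymmetry")

    xm = 0.5
    mid = {
        "Tr": 0.175 + 0.012 * hair,
        "G": 0.300 + 0.004 * hair,
        "N": 0.345,
        "Prn": 0.455 + 0.010 * nose,
        "Sn": 0.495 + 0.010 * nose,
        "Phi": 0.522 + 0.007 * nose,
        "Ls": 0.548 + 0.005 * nose,
        "Stm": 0.578,
        "Li": 0.607,
        "Pg": 0.655,
        "Gn": 0.693,
        "Me": 0.728,
    }
    pts = {name: (xm, y) for name, y in mid.items()}

    # Paired landmarks: (half-width offset, y).  A small asymmetry latent
    # widens one side and narrows the other; zero latents -> exact mirror.
    pairs = {
        "Go": (0.230 + 0.012 * jaw, 0.615),
        "Ch": (0.085 + 0.010 * mouth, 0.578),
        "Al": (0.052 + 0.004 * nose, 0.488 + 0.010 * nose),
        "Ex": (0.205 + 0.012 * eye, 0.375),
        "End": (0.098 + 0.008 * eye, 0.378),
    }
    for stem, (dx, y) in pairs.items():
        pts[f"{stem}L"] = (xm - dx * (1.0 + 0.03 * asym), y)
        pts[f"{stem}R"] = (xm + dx * (1.0 - 0.03 * asym), y)
    return pts


def _profile_fractions(p: SubjectParams) -> dict[str, tuple[float, float]]:
    """Profile (right-facing) landmark positions as fractions of (W, H)."""
    nose = p.latent("nose_length")
    jaw = p.latent("jaw_angle")
    hair = p.latent("hairline_height")
    mouth = p.latent("mouth_width")

    return {
        "Tr": (0.560, 0.175 + 0.012 * hair),
        "G": (0.665, 0.300 + 0.004 * hair),
        "N": (0.648, 0.345),
        "Prn": (0.730 + 0.012 * nose, 0.455 + 0.010 * nose),
        "Col": (0.705 + 0.010 * nose, 0.477 + 0.010 * nose),
        "Al": (0.655, 0.484 + 0.010 * nose),
        "Sn": (0.668, 0.496 + 0.010 * nose),
        "Phi": (0.672, 0.522),
        "Ls": (0.676 + 0.004 * mouth, 0.548),
        "Stm": (0.665, 0.578),
        "Li": (0.672 + 0.004 * mouth, 0.607),
        "Pg": (0.658, 0.655),
        "Gn": (0.640, 0.693),
        "Me": (0.605, 0.728),
        "Go": (0.330 - 0.012 * jaw, 0.615),
    }


def landmark_template(params: SubjectParams, view: str) -> list[PointAnnotation]:
    """Exact ground-truth landmark positions for one subject and view.

    Returns 22 (frontal) or 15 (profile) points in image pixel
    coordinates, in canonical schema order.
    """
    schema = get_schema(view)
    fr = (_frontal_fractions(params) if view == FRONTAL_VIEW
          else _profile_fractions(params))
    w, h = params.face_width_px, params.face_height_px
    coords = np.array([[fr[name][0] * w, fr[name][1] * h]
                       for name in schema.names])
    return points_from_array(coords, schema)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _skin_rgb(tone: float) -> tuple[int, int, int]:
    return (int(175 + 50 * tone), int(135 + 50 * tone), int(105 + 45 * tone))


def _darker(rgb: tuple[int, int, int], f: float) -> tuple[int, int, int]:
    return tuple(int(c * f) for c in rgb)


def _arc_points(cx, cy, a, b, t0, t1, n=60):
    t = np.linspace(t0, t1, n)
    return [(cx + a * math.cos(v), cy + b * math.sin(v)) for v in t]


def _background(w: int, h: int) -> np.ndarray:
    grad = np.linspace(225, 205, h, dtype=np.float32)[:, None]
    img = np.broadcast_to(grad, (h, w)).astype(np.uint8)
    return np.stack([img, img, np.clip(img + 6, 0, 255).astype(np.uint8)], axis=-1)


def _finalize(img: Image.Image, seed: int) -> np.ndarray:
    """Add deterministic sensor-like noise and return uint8 pixels."""
    arr = np.asarray(img, dtype=np.float32)
    rng = np.random.default_rng(seed)
    arr += rng.normal(0.0, 2.0, size=arr.shape).astype(np.float32)
    return np.clip(arr, 0, 255).astype(np.uint8)


def _render_frontal(p: SubjectParams) -> np.ndarray:
    w = int(round(p.face_width_px))
    h = int(round(p.face_height_px))
    fr = _frontal_fractions(p)

    def px(name):
        fx, fy = fr[name]
        return fx * w, fy * h

    skin = _skin_rgb(p.skin_tone)
    line = _darker(skin, 0.45)
    soft = _darker(skin, 0.80)
    hair_c = (70, 50, 35)
    lip = (170, 95, 95)
    lipline = (120, 55, 55)
    lw = max(3, w // 200)  # stroke width scales with resolution

    img = Image.fromarray(_background(w, h))
    dr = ImageDraw.Draw(img)

    # Head: ellipse through the jaw-width and chin landmarks.
    cx = 0.5 * w
    go_dx = (fr["GoR"][0] - fr["GoL"][0]) / 2 * w
    cy = fr["GoL"][1] * h - 0.25 * h
    a_head = go_dx * 1.18
    b_head = fr["Me"][1] * h - cy
    dr.ellipse([cx - a_head, cy - b_head, cx + a_head, cy + b_head],
               fill=skin, outline=line, width=lw)

    # Jaw contour: lower half-ellipse through GoL, Me, GoR.
    jaw_cy = fr["GoL"][1] * h
    jaw_b = fr["Me"][1] * h - jaw_cy
    jaw = _arc_points(cx, jaw_cy, go_dx, jaw_b, math.pi, 2 * math.pi)
    dr.line(jaw, fill=line, width=lw, joint="curve")

    # Hair: region between the skull top and a parabolic hairline through Tr.
    tr_x, tr_y = px("Tr")
    half = a_head * 0.92
    xs = np.linspace(cx - half, cx + half, 80)
    hairline = [(x, tr_y + 0.10 * h * ((x - cx) / half) ** 2) for x in xs]
    top = [(x, cy - b_head * math.sqrt(max(0.0, 1 - ((x - cx) / a_head) ** 2)))
           for x in xs[::-1]]
    dr.polygon(hairline + top, fill=hair_c)

    # Nose bridge G -> N -> Prn and tip/base structure.
    g = px("G"); n = px("N"); prn = px("Prn"); sn = px("Sn")
    dr.line([g, n, (prn[0], prn[1] - 0.01 * h)], fill=soft, width=lw)
    dr.ellipse([prn[0] - 0.016 * w, prn[1] - 0.016 * w,
                prn[0] + 0.016 * w, prn[1] + 0.016 * w],
               outline=soft, width=lw)
    # Nostril wings through AlL / AlR; alar base line through Sn.
    for side in ("AlL", "AlR"):
        ax, ay = px(side)
        inward = 0.011 * w if side == "AlL" else -0.011 * w
        dr.ellipse([ax + inward - 0.013 * w, ay - 0.013 * w,
                    ax + inward + 0.013 * w, ay + 0.013 * w],
                   outline=line, width=lw)
    dr.line([(px("AlL")[0], sn[1]), (px("AlR")[0], sn[1])], fill=soft, width=lw)

    # Eyes: almond from End to Ex corner, iris between; brows above.
    for en_n, ex_n in (("EndL", "ExL"), ("EndR", "ExR")):
        en = px(en_n); ex = px(ex_n)
        ecx, ecy = (en[0] + ex[0]) / 2, (en[1] + ex[1]) / 2
        ea = abs(ex[0] - en[0]) / 2
        upper = [(ecx + ea * math.cos(t), ecy - 0.55 * ea * math.sin(t))
                 for t in np.linspace(0, math.pi, 30)]
        lower = [(ecx + ea * math.cos(t), ecy + 0.40 * ea * math.sin(t))
                 for t in np.linspace(math.pi, 0, 30)]
        dr.polygon(upper + lower, fill=(245, 245, 245), outline=line, width=lw)
        r_iris = 0.45 * ea
        dr.ellipse([ecx - r_iris, ecy - r_iris, ecx + r_iris, ecy + r_iris],
                   fill=(80, 60, 45))
        dr.line([(en[0] - 0.2 * ea, ecy - 1.3 * ea),
                 (ex[0] + 0.2 * ea, ecy - 1.5 * ea)], fill=hair_c, width=lw + 1)

    # Mouth: upper lip (Ls), mouth line through ChL-Stm-ChR, lower lip (Li).
    chl = px("ChL"); chr_ = px("ChR"); ls = px("Ls")
    stm = px("Stm"); li = px("Li")
    xs_m = np.linspace(chl[0], chr_[0], 40)
    span = (chr_[0] - chl[0]) / 2
    mouth = [(x, stm[1] + 0.004 * h * (((x - cx) / span) ** 2 - 0.5))
             for x in xs_m]
    upper = [(x, ls[1] + (stm[1] - ls[1]) * ((x - cx) / span) ** 2)
             for x in xs_m[::-1]]
    dr.polygon(mouth + upper, fill=lip, outline=lipline, width=max(2, lw - 1))
    lower = [(x, li[1] + (stm[1] - li[1]) * ((x - cx) / span) ** 2)
             for x in xs_m]
    dr.polygon(mouth + lower[::-1], fill=lip, outline=lipline,
               width=max(2, lw - 1))
    dr.line(mouth, fill=lipline, width=lw)
    # Philtrum groove Sn -> Ls through Phi.
    dr.line([sn, ls], fill=soft, width=max(2, lw - 1))

    # Chin creases at Pg and Gn.
    for nm in ("Pg", "Gn"):
        x0, y0 = px(nm)
        dr.arc([x0 - 0.045 * w, y0 - 0.02 * h, x0 + 0.045 * w, y0 + 0.02 * h],
               20, 160, fill=soft, width=lw)

    return _finalize(img, p.rng_seed)


def _render_profile(p: SubjectParams) -> np.ndarray:
    w = int(round(p.face_width_px))
    h = int(round(p.face_height_px))
    fr = _profile_fractions(p)

    def px(name):
        fx, fy = fr[name]
        return fx * w, fy * h

    skin = _skin_rgb(p.skin_tone)
    line = _darker(skin, 0.45)
    soft = _darker(skin, 0.80)
    hair_c = (70, 50, 35)
    lw = max(3, w // 200)

    img = Image.fromarray(_background(w, h))
    dr = ImageDraw.Draw(img)

    # Facial silhouette through every midline landmark, top to bottom.
    g = px("G"); n = px("N"); prn = px("Prn"); col = px("Col")
    sn = px("Sn"); phi = px("Phi"); ls = px("Ls"); stm = px("Stm")
    li = px("Li"); pg = px("Pg"); gn = px("Gn"); me = px("Me")
    go = px("Go")
    forehead_top = (0.565 * w, 0.205 * h)
    silhouette = [
        forehead_top,
        (0.630 * w, 0.248 * h),
        g,
        ((g[0] + n[0]) / 2 + 0.004 * w, (g[1] + n[1]) / 2),
        n,
        (n[0] + 0.35 * (prn[0] - n[0]), n[1] + 0.45 * (prn[1] - n[1])),
        (n[0] + 0.72 * (prn[0] - n[0]), n[1] + 0.80 * (prn[1] - n[1])),
        prn, col, sn,
        (sn[0] + 0.004 * w, (sn[1] + phi[1]) / 2),
        phi, ls,
        (ls[0] - 0.004 * w, (ls[1] + stm[1]) / 2),
        stm,
        (li[0] - 0.004 * w, (stm[1] + li[1]) / 2),
        li,
        (li[0] - 0.006 * w, (li[1] + pg[1]) / 2),
        pg, gn, me,
    ]

    # Head/skull: ellipse behind the silhouette, plus a jawline to Gonion.
    cx, cy = 0.46 * w, 0.42 * h
    a_head, b_head = 0.26 * w, 0.30 * h
    dr.ellipse([cx - a_head, cy - b_head, cx + a_head, cy + b_head],
               fill=skin, outline=None)
    # Face region fill: silhouette closed through the jaw and back of head.
    face_poly = silhouette + [go, (0.33 * w, 0.40 * h)]
    dr.polygon(face_poly, fill=skin)
    dr.line(silhouette, fill=line, width=lw, joint="curve")
    dr.line([me, go], fill=line, width=lw)  # jawline through Me and Go
    dr.line([go, (go[0] - 0.01 * w, go[1] - 0.06 * h)], fill=line, width=lw)

    # Hair mass over the skull, lower boundary a parabola with vertex at Tr.
    tr = px("Tr")
    xs = np.linspace(cx - a_head, tr[0] + 0.08 * w, 60)
    hairline = [(x, tr[1] + 0.10 * h * ((x - tr[0]) / (0.30 * w)) ** 2)
                for x in xs]
    top = [(x, cy - 1.06 * b_head * math.sqrt(
        max(0.0, 1 - ((x - cx) / (1.02 * a_head)) ** 2))) for x in xs[::-1]]
    dr.polygon(hairline + top, fill=hair_c)

    # Eye, brow, nostril, ear.
    ex, ey = 0.575 * w, 0.378 * h
    ea = 0.030 * w
    dr.polygon([(ex - ea, ey), (ex + ea, ey - 0.4 * ea),
                (ex + ea, ey + 0.4 * ea)], fill=(245, 245, 245),
               outline=line, width=max(2, lw - 1))
    dr.ellipse([ex - 0.35 * ea, ey - 0.35 * ea, ex + 0.35 * ea,
                ey + 0.35 * ea], fill=(80, 60, 45))
    dr.line([(ex - 1.4 * ea, ey - 1.6 * ea), (ex + 1.4 * ea, ey - 1.9 * ea)],
            fill=hair_c, width=lw + 1)
    al = px("Al")
    dr.ellipse([al[0] - 0.024 * w, al[1] - 0.013 * w,
                al[0] + 0.002 * w, al[1] + 0.013 * w],
               outline=line, width=lw)
    dr.ellipse([0.330 * w, 0.430 * h, 0.395 * w, 0.530 * h],
               outline=line, width=lw)

    # Mouth line through Stm; lip shading at Ls / Li.
    dr.line([(stm[0] - 0.055 * w, stm[1] + 0.004 * h), stm],
            fill=(120, 55, 55), width=lw)

    return _finalize(img, p.rng_seed + 1)


def render_view(params: SubjectParams, view: str) -> AnnotatedImage:
    """Render one subject's view with its exact template landmarks attached."""
    if view == FRONTAL_VIEW:
        pixels = _render_frontal(params)
    elif view == PROFILE_VIEW:
        pixels = _render_profile(params)
    else:
        get_schema(view)  # raises SchemaError
    h, w = pixels.shape[:2]
    return AnnotatedImage(
        subject_id=params.subject_id,
        view=view,
        pixels=pixels,
        width=w,
        height=h,
        landmarks=landmark_template(params, view),
    )


def simulate_annotator(truth: list[PointAnnotation], model: AnnotatorModel,
                       scale: float = BASE_SCALE_MM_PER_PX
                       ) -> list[PointAnnotation]:
    """One manual annotation round: truth plus isotropic Gaussian jitter.

    Jitter is specified in millimetres per axis and converted to pixels
    through the export scale, so repeatability statistics are honest in
    physical units regardless of image resolution.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(model.rng_seed)
    sd_px = model.jitter_sd_mm / scale
    coords = np.array([[pt.x, pt.y] for pt in truth], dtype=float)
    coords = coords + rng.normal(0.0, sd_px, size=coords.shape)
    return [PointAnnotation(pt.name, float(x), float(y))
            for pt, (x, y) in zip(truth, coords)]


def generate_cohort(n_subjects: int, master_seed: int,
                    views: tuple[str, ...] = (FRONTAL_VIEW, PROFILE_VIEW)
                    ) -> list[AnnotatedImage]:
    """Generate the full synthetic cohort: one image per view per subject.

    The result is a pure function of (n_subjects, master_seed); images
    appear subject by subject, frontal before profile.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cohort = []
    for i in range(n_subjects):
        params = sample_subject(i, master_seed)
        for view in views:
            cohort.append(render_view(params, view))
    return cohort
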