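import numpy as np
import pytest

import actsparse as asp


@pytest.fixture(scope="session")
def fixture_net():
    return asp.fixture_backend(42)


@pytest.fixture(scope="session")
def class_image_run():
    """100 fixture images (half sparse_dots, half dense_noise) with
    class-driven scores, encoded through the fixture network."""
    seed = 7
    n = 100
    imgs = (asp.generate_fixture_images(n // 2, "sparse_dots", seed)
            + asp.generate_fixture_images(n // 2, "dense_noise", seed))
    rng = np.random.default_rng([seed, 29])
    raw = np.clip(np.concatenate([rng.normal(4.0, 0.5, n // 2),
                                  rng.normal(1.0, 0.5, n // 2)]), 0.0, 5.0)
    backend = asp.fixture_backend(seed)
    acts = asp.encode_images(imgs, backend)
    return {"images": imgs, "scores": raw, "backend": backend, "acts": acts}


@pytest.fixture()
def manifest_dir(tmp_path):
    """Write a tiny valid manifest with three 8x8 PNG images."""
    from PIL import Image

    img_dir = tmp_path / "img"
    img_dir.mkdir()
    rng = np.random.default_rng(0)
    names = []
    for i in range(3):
        arr = rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)
        name = f"im{i}.png"
        Image.fromarray(arr).save(img_dir / name)
        names.append(f"img/{name}")
    lines = ["# dataset_name: demo", "# scale_min: 1", "# scale_max: 7",
             "image_path,score", f"{names[0]},1.0", f"{names[1]},4.2",
             f"{names[2]},7.0"]
    (tmp_path / "manifest.csv").write_text("\n".join(lines) + "\n")
    return tmp_path
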