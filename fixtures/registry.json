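{
  "fixtures": [
    {
      "command": "python -c \"from seedxray.fixtures import regenerate_fixtures; regenerate_fixtures('fixtures')\"",
      "name": "classes.txt",
      "path": "classes.txt",
      "seed": 7,
      "sha256": "ae587cdcc65c2f648665a764582d156bd2c41d6718736846e3fb5e302210e24b"
    },
    {
      "command": "python -c \"from seedxray.fixtures import regenerate_fixtures; regenerate_fixtures('fixtures')\"",
      "name": "golden_metrics.csv",
      "path": "golden_metrics.csv",
      "seed": 7,
      "sha256": "3f98288ae8e8cdf732ab7adc0bed14100e35e9078fd1d5dc7c82483a357044a7"
    },
    {
      "command": "python -c \"from seedxray.fixtures import regenerate_fixtures; regenerate_fixtures('fixtures')\"",
      "name": "golden_voc.xml",
      "path": "golden_voc.xml",
      "seed": 7,
      "sha256": "4d7d51bcd10b75a5e2de4f246feeb707d9dab935ed4d5320a344bee173b3f0e9"
    },
    {
      "command": "python -c \"from seedxray.fixtures import regenerate_fixtures; regenerate_fixtures('fixtures')\"",
      "name": "golden_yolo.txt",
      "path": "golden_yolo.txt",
      "seed": 7,
      "sha256": "d02de73dcc945755b3ccc1d64413e12a2948d08bc0e69e08d3731f31db218342"
    },
    {
      "command": "python -c \"from seedxray.fixtures import regenerate_fixtures; regenerate_fixtures('fixtures')\"",
      "name": "manifest.csv",
      "path": "manifest.csv",
      "seed": 7,
      "sha256": "e842f02632b7bc7aff841bb38aa8ec2fcf9c42bfb202ceb827b9072a48a2a3d9"
    },
    {
      "command": "python -c \"from seedxray.fixtures import regenerate_fixtures; regenerate_fixtures('fixtures')\"",
      "name": "truth.csv",
      "path": "truth.csv",
      "seed": 7,
      "sha256": "df349465c3c2cfcdd694971cc274df6bb4dfba6be2a4f8459a4715e3efc39481"
    }
  ]
}
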