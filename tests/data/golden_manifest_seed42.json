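{
 "artifacts": {
  "classify/assignments.tsv": "b3c75d3590d229e3de210fe7447163e8155f49313f430bee2e77418a1b7985c0",
  "classify/stages.json": "a975acbe9b3a1d51a698e3233265d35b8ad939b63f35d2477c1a25a8d6e786d5",
  "classify/tree1.nwk": "b9bed6fab8382cfd064edb13cd2f604ce948c77563a0f74c58f1677b3b2a2a56",
  "classify/tree2.nwk": "b7ace55fd02d604032bb2c056fbb54254346d5ba70fc0e68e29f4c9f3a09b9fb",
  "expression/results.tsv": "4c291cb4c06213a040528d2d45ff59424572bd06ca83da642a9a111c17418fd5",
  "expression/trends.tsv": "61dcb4b83c38be2f1c58a2cf0e373ad85401ed17abc4d63e593b85919d34214d",
  "homology/clusters.tsv": "2d3b584e865d0e97f5c0e938f69d9fa29233a4261c0f57063d1dfca68f9832a0",
  "homology/orthologs.tsv": "849edad2717684ba5795118f1cb90bfe3babc54e39d7395ad6fb7ee6581c2b11",
  "homology/paralogs_query.tsv": "8ef5d6285f3af968b70364a3882a2665a201c1070f3dd0ef3d8bb7103ccf43a3",
  "homology/paralogs_reference.tsv": "4aefd314fb1a395d53de4a1954d97e7853bc4d7546a36c124c5556434af1fece",
  "inputs/anchors.fasta": "6959b1fdda5833692a5f843689de8ace3b156aa06127f695a0ae5d1ccceb40f4",
  "inputs/anchors.tsv": "302338b359877c9c972c5ac3cbec14fca5fd4ae0efb78c49d17ef9dc75062806",
  "inputs/cds.fasta": "cf4ce8d7467a399eb60203dd248e0edc5a29220e8eefda0b7da611ada2d77457",
  "inputs/ct.tsv": "26862458f1c52892ad4a715e597289626d8ee895181124eb9b15c3e6f91bbed4",
  "inputs/genes.gff3": "32ce58df0781d37ecb0cdc4caf1adc8b3a14dcfae547c96c929611ecc707a9e6",
  "inputs/proteome.fasta": "41f109ada0dae5e320cf53497cfc559e1ae75b33d64e363d979816eabcfb3d0f",
  "inputs/seed_alignment.fasta": "13101f7341959249a4a8fe1e41565a9c468bea188cff903e4763100d84de9a05",
  "inputs/truth.json": "96e2b396f9f10a639eef3034ac735254470af5ae23fdfd371c54f86358acabb5",
  "motifs/architectures.tsv": "bedbc0f6b056a4713a95654f362641697e402481fb16cfd62ee1dafa72b9485f",
  "motifs/conservation.tsv": "ee0323005d028c7846f8cd42f892b4537c0edfa4ad269f6da5754c48b8a8bd24",
  "motifs/logo_m1.svg": "6231fda01fda2d950658fd618675a43d8fc3dce358ce938eb7554cba61be4304",
  "motifs/logo_m2.svg": "4f7a169affeec737fdfc7b1ecfc88f17b46eae5a46cbd948718a2a91e225bacb",
  "motifs/logo_m3.svg": "0d6b295685d0454a41218284865b4104713d269e6a72b869013a4c53d508c66e",
  "motifs/logo_m4.svg": "597969e01d876d140ae7ef3590b8fdfa86a1e9a2e78b6efb5bbee06fb9162786",
  "motifs/logo_m5.svg": "43d91f3117ce093fe2c3159c50b3d5afbe81843cb862e3f19209b69f472cd49e",
  "motifs/motifs_meme.txt": "ad3b11b7216de223fb6ce4fbc1e8417cec3434f5d62b840c01dc5640af3603ae",
  "motifs/occurrences.tsv": "121f82dc9c08dde869182e51c79992eb1543a00425412db0b7ac04479e74e8bc",
  "protparam/physchem.tsv": "c86c6739abff84b97a4da7dacf7e58c8f3ee8c0b436c56bc3c067c13a335f49e",
  "protparam/summary.json": "c2aae9ec2ac319b10ed57df427c38052553f0ff005d282d1eb95361890a18389",
  "scan/architectures.tsv": "9c49df56ae00fa209e30f89cbc9adb372150ef19ddc8262b87ba3295d4246a99",
  "scan/census.json": "617c31db44bc892ee8f80e338256d7d9de2839474d5456be27ebea9b87fffca1",
  "structure/chromosomes.svg": "2cc0e680c494252ac094de05456a70e9d1d36a6327e128e1a91df99a1cff5b52",
  "structure/distribution.tsv": "6e40c767fbbb41d2ff9428e4331e44c13549f1389e4f6024dd87a2c8070ce027",
  "structure/structures.tsv": "141586dd70f22c57d8c1dbccd5b06ba3c18bf5a91491bd4385ea9f5c672e2207"
 },
 "seed": 42
}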