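{
  "cross.csv": "2a2bcad76f2cb3527695ecaad5ff94b06b352a728c7a9570bf852e74616f7c4d",
  "genotypes.vcf": "9a6dd53d0bb77f6c2ca1e235b870200ad49899fb93d3b32d81d36a47f685b7f6",
  "samples.csv": "f0cbd693edc6c6eedc6570932698d0e8300a56326cc0d541d11f4c89d8cfc28a",
  "truth.json": "0bfd4253e0a24b062067bf4904da07c9c1f3ddd65480b25cdb50e01343c22c90",
  "vertebrae.csv": "f6c1e6d72f6e8ed922380f44bc0d1f7cb178f05641be3cca283efe09fc7371ab"
}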