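id	primitive	semanticClass
12921003	1	clinical_region
22943007	0	structure
281902004	1	cavity
43799004	1	cavity
609617007	0	segment
67734004	0	segment
816092008	0	cross_section
816094009	0	cross_section
816991004	1	cavity
818981001	0	cross_section
818983003	1	clinical_region
818984009	1	clinical_region
818985005	0	segment
818987002	1	cavity
827003001	0	wall
X-abdomen-proper-segment-of-trunk-e	1	entire
X-abdomen-proper-segment-of-trunk-p	0	part
X-abdominal-aorta-e	1	entire
X-abdominal-aorta-p	0	part
X-abdominal-aorta-s	0	structure
X-abdominal-cross-sectional-segment-of-trunk-e	1	entire
X-abdominal-cross-sectional-segment-of-trunk-p	0	part
X-abdominal-proper-content	1	content
X-abdominopelvic-content	1	content
X-abdominopelvic-cross-section-e	1	entire
X-abdominopelvic-cross-section-p	0	part
X-abdominopelvic-cross-section-s	0	cross_section
X-abdominopelvic-segment-e	1	entire
X-abdominopelvic-segment-p	0	part
X-abdominopelvic-segment-s	0	segment
X-anal-canal-e	1	entire
X-anal-canal-p	0	part
X-anal-canal-s	0	structure
X-anterior-abdominal-wall-e	1	entire
X-anterior-abdominal-wall-p	0	part
X-anterior-abdominal-wall-s	0	wall
X-aorta-e	1	entire
X-aorta-p	0	part
X-aorta-s	0	structure
X-arch-of-aorta-e	1	entire
X-arch-of-aorta-p	0	part
X-arch-of-aorta-s	0	structure
X-chest-wall-e	1	entire
X-chest-wall-p	0	part
X-chest-wall-s	0	wall
X-ct-of-abdomen	0	procedure
X-ct-of-abdomen-and-pelvis	0	procedure
X-ct-of-pelvis	0	procedure
X-descending-colon-e	1	entire
X-descending-colon-p	0	part
X-descending-colon-s	0	structure
X-digestive-system-e	1	entire
X-digestive-system-p	0	part
X-digestive-system-s	0	structure
X-disorder	1	disorder
X-disorder-of-abdomen-proper	0	disorder
X-disorder-of-abdominopelvic-segment	0	disorder
X-disorder-of-liver	0	disorder
X-disorder-of-urinary-bladder	0	disorder
X-disorder-of-uterus	0	disorder
X-external-genitalia-e	1	entire
X-external-genitalia-p	0	part
X-external-genitalia-s	0	structure
X-fallopian-tube-e	1	entire
X-fallopian-tube-p	0	part
X-fallopian-tube-s	0	structure
X-false-or-true-pelvis-cavity	1	cavity
X-false-pelvis-cavity	1	cavity
X-false-pelvis-content	1	content
X-iliac-colon-e	1	entire
X-iliac-colon-p	0	part
X-iliac-colon-s	0	structure
X-intra-abdominal-proper	1	structure
X-intra-abdominopelvic	1	structure
X-intra-thoracic	1	structure
X-intra-true-pelvis	1	structure
X-large-intestine-e	1	entire
X-large-intestine-p	0	part
X-large-intestine-s	0	structure
X-liver-e	1	entire
X-liver-p	0	part
X-liver-s	0	structure
X-lobe-of-liver-e	1	entire
X-lobe-of-liver-p	0	part
X-lobe-of-liver-s	0	structure
X-lumbar-vertebral-column-e	1	entire
X-lumbar-vertebral-column-p	0	part
X-lumbar-vertebral-column-s	0	structure
X-ovary-e	1	entire
X-ovary-p	0	part
X-ovary-s	0	structure
X-parenchyma-of-liver-e	1	entire
X-parenchyma-of-liver-p	0	part
X-parenchyma-of-liver-s	0	structure
X-pelvic-cross-sectional-segment-of-trunk-e	1	entire
X-pelvic-cross-sectional-segment-of-trunk-p	0	part
X-pelvic-diaphragm-e	1	entire
X-pelvic-diaphragm-p	0	part
X-pelvic-diaphragm-s	0	wall
X-pelvic-portion-of-ureter-e	1	entire
X-pelvic-portion-of-ureter-p	0	part
X-pelvic-portion-of-ureter-s	0	structure
X-pelvic-segment-of-trunk-e	1	entire
X-pelvic-segment-of-trunk-p	0	part
X-pelvic-wall-e	1	entire
X-pelvic-wall-p	0	part
X-pelvic-wall-s	0	wall
X-perineum-e	1	entire
X-perineum-p	0	part
X-perineum-s	0	structure
X-posterior-wall-of-abdomen-proper-e	1	entire
X-posterior-wall-of-abdomen-proper-p	0	part
X-presacral-space-e	1	entire
X-presacral-space-p	0	part
X-presacral-space-s	0	structure
X-procedure	1	procedure
X-prostate-e	1	entire
X-prostate-p	0	part
X-prostate-s	0	structure
X-puboprostatic-ligament-e	1	entire
X-puboprostatic-ligament-p	0	part
X-puboprostatic-ligament-s	0	structure
X-rectum-e	1	entire
X-rectum-p	0	part
X-rectum-s	0	structure
X-retropubic-space-e	1	entire
X-retropubic-space-p	0	part
X-retropubic-space-s	0	structure
X-seminal-vesicle-e	1	entire
X-seminal-vesicle-p	0	part
X-seminal-vesicle-s	0	structure
X-sigmoid-colon-e	1	entire
X-sigmoid-colon-p	0	part
X-sigmoid-colon-s	0	structure
X-t9-t12-cross-sectional-band-of-trunk-e	1	entire
X-t9-t12-cross-sectional-band-of-trunk-p	0	part
X-t9-t12-cross-sectional-band-of-trunk-s	0	cross_section
X-thoracic-content	1	content
X-thoracic-cross-sectional-segment-of-trunk-e	1	entire
X-thoracic-cross-sectional-segment-of-trunk-p	0	part
X-thoracic-diaphragm-e	1	entire
X-thoracic-diaphragm-p	0	part
X-thoracic-diaphragm-s	0	wall
X-thoracic-segment-of-trunk-e	1	entire
X-thoracic-segment-of-trunk-p	0	part
X-true-pelvis-content	1	content
X-trunk-e	1	entire
X-trunk-p	0	part
X-ureter-e	1	entire
X-ureter-p	0	part
X-ureter-s	0	structure
X-urinary-bladder-e	1	entire
X-urinary-bladder-p	0	part
X-urinary-bladder-s	0	structure
X-uterus-e	1	entire
X-uterus-p	0	part
X-uterus-s	0	structure
X-wall-of-abdominal-proper-segment-of-trunk-e	1	entire
X-wall-of-abdominal-proper-segment-of-trunk-p	0	part
X-wall-of-abdominal-proper-segment-of-trunk-s	0	wall
X-wall-of-abdominopelvic-segment-of-trunk-e	1	entire
X-wall-of-abdominopelvic-segment-of-trunk-p	0	part
X-wall-of-abdominopelvic-segment-of-trunk-s	0	wall
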