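node_id,network,excluded
ROI_001,DMN,0
ROI_002,DMN,0
ROI_003,DMN,0
ROI_004,DMN,0
ROI_005,DMN,0
ROI_006,DMN,0
ROI_007,DMN,0
ROI_008,DMN,0
ROI_009,DMN,0
ROI_010,DMN,0
ROI_011,DMN,0
ROI_012,DMN,0
ROI_013,DMN,0
ROI_014,DMN,0
ROI_015,DMN,0
ROI_016,DMN,0
ROI_017,DMN,0
ROI_018,DMN,0
ROI_019,DMN,0
ROI_020,DMN,0
ROI_021,DMN,0
ROI_022,DMN,0
ROI_023,DMN,0
ROI_024,DMN,0
ROI_025,DMN,0
ROI_026,DMN,0
ROI_027,DMN,0
ROI_028,DMN,0
ROI_029,DMN,0
ROI_030,DMN,0
ROI_031,DMN,0
ROI_032,DMN,0
ROI_033,DMN,0
ROI_034,DMN,0
ROI_035,MFN,0
ROI_036,MFN,0
ROI_037,MFN,0
ROI_038,MFN,0
ROI_039,MFN,0
ROI_040,MFN,0
ROI_041,MFN,0
ROI_042,MFN,0
ROI_043,MFN,0
ROI_044,MFN,0
ROI_045,MFN,0
ROI_046,MFN,0
ROI_047,MFN,0
ROI_048,MFN,0
ROI_049,MFN,0
ROI_050,MFN,0
ROI_051,MFN,0
ROI_052,MFN,0
ROI_053,MFN,0
ROI_054,MFN,0
ROI_055,MFN,0
ROI_056,MFN,0
ROI_057,FPN,0
ROI_058,FPN,0
ROI_059,FPN,0
ROI_060,FPN,0
ROI_061,FPN,0
ROI_062,FPN,0
ROI_063,FPN,0
ROI_064,FPN,0
ROI_065,FPN,0
ROI_066,FPN,0
ROI_067,FPN,0
ROI_068,FPN,0
ROI_069,FPN,0
ROI_070,FPN,0
ROI_071,FPN,0
ROI_072,FPN,0
ROI_073,FPN,0
ROI_074,FPN,0
ROI_075,FPN,0
ROI_076,FPN,0
ROI_077,FPN,0
ROI_078,FPN,0
ROI_079,FPN,0
ROI_080,FPN,0
ROI_081,FPN,0
ROI_082,FPN,0
ROI_083,FPN,0
ROI_084,FPN,0
ROI_085,limbic,0
ROI_086,limbic,0
ROI_087,limbic,0
ROI_088,limbic,0
ROI_089,limbic,0
ROI_090,limbic,0
ROI_091,limbic,0
ROI_092,limbic,0
ROI_093,limbic,0
ROI_094,limbic,0
ROI_095,limbic,0
ROI_096,limbic,0
ROI_097,limbic,0
ROI_098,limbic,0
ROI_099,limbic,0
ROI_100,limbic,0
ROI_101,limbic,0
ROI_102,limbic,0
ROI_103,limbic,0
ROI_104,limbic,0
ROI_105,limbic,0
ROI_106,limbic,0
ROI_107,limbic,0
ROI_108,limbic,0
ROI_109,motor,0
ROI_110,motor,0
ROI_111,motor,0
ROI_112,motor,0
ROI_113,motor,0
ROI_114,motor,0
ROI_115,motor,0
ROI_116,motor,0
ROI_117,motor,0
ROI_118,motor,0
ROI_119,motor,0
ROI_120,motor,0
ROI_121,motor,0
ROI_122,motor,0
ROI_123,motor,0
ROI_124,motor,0
ROI_125,motor,0
ROI_126,motor,0
ROI_127,motor,0
ROI_128,motor,0
ROI_129,motor,0
ROI_130,motor,0
ROI_131,motor,0
ROI_132,motor,0
ROI_133,motor,0
ROI_134,motor,0
ROI_135,motor,0
ROI_136,visual_I,0
ROI_137,visual_I,0
ROI_138,visual_I,0
ROI_139,visual_I,0
ROI_140,visual_I,0
ROI_141,visual_I,0
ROI_142,visual_I,0
ROI_143,visual_I,0
ROI_144,visual_I,0
ROI_145,visual_I,0
ROI_146,visual_I,0
ROI_147,visual_I,0
ROI_148,visual_I,0
ROI_149,visual_I,0
ROI_150,visual_I,0
ROI_151,visual_I,0
ROI_152,visual_I,0
ROI_153,visual_I,0
ROI_154,visual_I,0
ROI_155,visual_I,0
ROI_156,visual_II,0
ROI_157,visual_II,0
ROI_158,visual_II,0
ROI_159,visual_II,0
ROI_160,visual_II,0
ROI_161,visual_II,0
ROI_162,visual_II,0
ROI_163,visual_II,0
ROI_164,visual_II,0
ROI_165,visual_II,0
ROI_166,visual_II,0
ROI_167,visual_II,0
ROI_168,visual_II,0
ROI_169,visual_II,0
ROI_170,visual_II,0
ROI_171,visual_II,0
ROI_172,visual_II,0
ROI_173,visual_II,0
ROI_174,visual_II,0
ROI_175,visual_II,0
ROI_176,visual_II,0
ROI_177,visual_assoc,0
ROI_178,visual_assoc,0
ROI_179,visual_assoc,0
ROI_180,visual_assoc,0
ROI_181,visual_assoc,0
ROI_182,visual_assoc,0
ROI_183,visual_assoc,0
ROI_184,visual_assoc,0
ROI_185,visual_assoc,0
ROI_186,visual_assoc,0
ROI_187,visual_assoc,0
ROI_188,visual_assoc,0
ROI_189,visual_assoc,0
ROI_190,visual_assoc,0
ROI_191,visual_assoc,0
ROI_192,visual_assoc,0
ROI_193,visual_assoc,0
ROI_194,visual_assoc,0
ROI_195,visual_assoc,0
ROI_196,visual_assoc,0
ROI_197,visual_assoc,0
ROI_198,visual_assoc,0
ROI_199,visual_assoc,0
ROI_200,BGN,0
ROI_201,BGN,0
ROI_202,BGN,0
ROI_203,BGN,0
ROI_204,BGN,0
ROI_205,BGN,0
ROI_206,BGN,0
ROI_207,BGN,0
ROI_208,BGN,0
ROI_209,BGN,0
ROI_210,BGN,0
ROI_211,BGN,0
ROI_212,BGN,0
ROI_213,BGN,0
ROI_214,BGN,0
ROI_215,BGN,0
ROI_216,BGN,0
ROI_217,BGN,0
ROI_218,BGN,0
ROI_219,BGN,0
ROI_220,cerebellum,1
ROI_221,cerebellum,1
ROI_222,cerebellum,1
ROI_223,cerebellum,1
ROI_224,cerebellum,1
ROI_225,cerebellum,1
ROI_226,cerebellum,1
ROI_227,cerebellum,1
ROI_228,cerebellum,1
ROI_229,cerebellum,1
ROI_230,cerebellum,1
ROI_231,cerebellum,1
ROI_232,cerebellum,1
ROI_233,cerebellum,1
ROI_234,cerebellum,1
ROI_235,cerebellum,1
ROI_236,cerebellum,1
ROI_237,cerebellum,1
ROI_238,cerebellum,1
ROI_239,cerebellum,1
ROI_240,cerebellum,1
ROI_241,cerebellum,1
ROI_242,cerebellum,1
ROI_243,cerebellum,1
ROI_244,cerebellum,1
ROI_245,cerebellum,1
ROI_246,cerebellum,1
ROI_247,cerebellum,1
ROI_248,cerebellum,1
ROI_249,cerebellum,1
ROI_250,cerebellum,1
ROI_251,cerebellum,1
ROI_252,cerebellum,1
ROI_253,cerebellum,1
ROI_254,cerebellum,1
ROI_255,cerebellum,1
ROI_256,cerebellum,1
ROI_257,cerebellum,1
ROI_258,cerebellum,1
ROI_259,cerebellum,1
ROI_260,cerebellum,1
ROI_261,cerebellum,1
ROI_262,cerebellum,1
ROI_263,cerebellum,1
ROI_264,cerebellum,1
ROI_265,cerebellum,1
ROI_266,cerebellum,1
ROI_267,cerebellum,1
ROI_268,cerebellum,1
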