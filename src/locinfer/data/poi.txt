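故宫
天府广场
外滩
天安门
黄鹤楼
兵马俑
洪崖洞
宽窄巷子
鼓浪屿
东方明珠
趵突泉
滇池
千岛湖
橘子洲
莫高窟
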