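了
着
很
然后
但是
因为
所以
如果
虽然
已经
可以
觉得
什么
一个
没有
时候
这样
那样
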